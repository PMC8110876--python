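"""Brute-force reference implementations, independent of the package's
compiled matchers: plain token-list scanning with no indexing or variant
precomputation.  Used as oracles by the query-engine equivalence tests."""

import re
import unicodedata


def naive_tokens(text):
    out, i, n = [], 0, len(text)
    text = unicodedata.normalize("NFC", text).casefold()
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "#" and i + 1 < n and re.match(r"\w", text[i + 1]):
            j = i + 1
            while j < n and re.match(r"\w", text[j]):
                j += 1
            out.append(text[i:j])
            i = j
        elif re.match(r"\w", ch):
            j = i
            while j < n and re.match(r"\w", text[j]):
                j += 1
            out.append(text[i:j])
            i = j
        else:
            i += 1
    return out


def naive_term_present(tokens, term, hashtag_variants):
    """Scan every start position for the term's token sequence."""
    candidates = [naive_tokens(term)]
    if hashtag_variants:
        seq = candidates[0]
        if len(seq) == 1 and not seq[0].startswith("#"):
            candidates.append(["#" + seq[0]])
    for seq in candidates:
        if not seq:
            continue
        for start in range(len(tokens) - len(seq) + 1):
            if tokens[start : start + len(seq)] == seq:
                return True
    return False


def naive_match(text, standalone, anchors, contexts, exclusions, hashtags=True):
    tokens = naive_tokens(text)

    def any_present(terms):
        return any(naive_term_present(tokens, t, hashtags) for t in terms)

    positive = any_present(standalone) or (
        any_present(anchors) and any_present(contexts)
    )
    return positive and not any_present(exclusions)
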
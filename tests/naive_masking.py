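"""Independent, deliberately naive re-implementation of the masking loop.

Used only as an oracle: plain dictionaries, per-cell loops and Fraction
arithmetic, no shared code with the package's vectorized fixpoint.
"""
from fractions import Fraction


def naive_fixpoint(states, br, rr, bd=0.0, sizes=None, mask_all_absent=True):
    """states: list of rows (pairs), each a list of (i, j) char tuples.

    Returns (kept_pair_indices, kept_bin_indices) or None when every pair is
    masked.  Thresholds are compared as exact fractions.
    """
    n_pairs = len(states)
    n_bins = len(states[0]) if n_pairs else 0
    br = Fraction(br).limit_denominator(100)
    rr = Fraction(rr).limit_denominator(100)
    pairs = set(range(n_pairs))
    bins = set(range(n_bins))

    def unambiguous(s):
        return "?" not in s

    while True:
        changed = False
        # step 1: replicate reliability
        for y in sorted(pairs):
            tot = sum(1 for x in bins if unambiguous(states[y][x]))
            rep = sum(
                1 for x in bins if unambiguous(states[y][x]) and states[y][x][0] == states[y][x][1]
            )
            if tot == 0 or Fraction(rep, tot) <= rr:
                pairs.discard(y)
                changed = True
        if not pairs:
            return None
        # step 2: bin reliability / presence rules
        for x in sorted(bins):
            col = [states[y][x] for y in pairs]
            unamb = [s for s in col if unambiguous(s)]
            tot = len(unamb)
            rep = sum(1 for s in unamb if s[0] == s[1])
            n11 = sum(1 for s in col if s == ("1", "1"))
            all00 = tot > 0 and all(s == ("0", "0") for s in unamb)
            masked = False
            if tot == 0:
                masked = True
            elif Fraction(rep, tot) <= br:
                masked = True
            elif n11 == 0:
                if mask_all_absent or not all00:
                    masked = True
            if masked:
                bins.discard(x)
                changed = True
        # step 3: bin distance on the survivors
        if sizes is not None:
            ordered = sorted(bins, key=lambda x: sizes[x])
            drop = set()
            for b1, b2 in zip(ordered, ordered[1:]):
                if sizes[b2] - sizes[b1] <= bd + 1e-9:
                    drop.update((b1, b2))
            if drop & bins:
                bins -= drop
                changed = True
        if not changed:
            return sorted(pairs), sorted(bins)


def naive_error_rates(states, pairs, bins):
    """(mismatch rate over unambiguous, Jaccard rate) by direct counting."""
    n01 = n10 = n00 = n11 = 0
    for y in pairs:
        for x in bins:
            s = states[y][x]
            if s == ("0", "1"):
                n01 += 1
            elif s == ("1", "0"):
                n10 += 1
            elif s == ("0", "0"):
                n00 += 1
            elif s == ("1", "1"):
                n11 += 1
    bonin = Fraction(n01 + n10, n00 + n11 + n01 + n10)
    jaccard = Fraction(n01 + n10, n11 + n01 + n10)
    return bonin, jaccard
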
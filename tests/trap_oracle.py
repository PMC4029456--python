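"""Brute-force TRAP reference, written independently of the package's
vectorized implementation: explicit position-by-position loops over
both strands.  Used as the oracle in equivalence tests."""

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def trap_oracle(matrix, sequence, lam=0.7, pseudocount=1.0, r0=None):
    """Expected occupancy by explicit enumeration of every window."""
    m = len(matrix)
    if r0 is None:
        r0 = math.exp(0.584 * m - 5.66)
    probs = []
    for row in matrix:
        total = sum(row) + 4 * pseudocount
        probs.append([(c + pseudocount) / total for c in row])

    def strand_sum(seq):
        total = 0.0
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if "N" in window:
                continue
            energy = 0.0
            for j, base in enumerate(window):
                best = max(probs[j])
                energy += math.log(best / probs[j][_IDX[base]])
            energy /= lam
            x = r0 * math.exp(-energy)
            total += x / (1.0 + x)
        return total

    seq = sequence.upper()
    rc = "".join(_COMP[b] for b in reversed(seq))
    return strand_sum(seq) + strand_sum(rc)
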
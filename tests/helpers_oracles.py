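"""Independent reference implementations used as test oracles.

These are deliberately plain, loop-based renditions of the textbook
definitions, written separately from the package's optimized paths so the
two can disagree.
"""

from Bio.Align import substitution_matrices

_BLOSUM = {}


def _subst(scheme):
    if isinstance(scheme.substitution, str):
        name = scheme.substitution.upper()
        if name not in _BLOSUM:
            _BLOSUM[name] = substitution_matrices.load(name)
        mat = _BLOSUM[name]

        def score(x, y):
            return float(mat[x, y])

    else:
        match, mismatch = scheme.substitution

        def score(x, y):
            return float(match if x == y else mismatch)

    return score


def sw_score_reference(seq_a: str, seq_b: str, scheme) -> float:
    """Plain Gotoh dynamic program for local alignment with affine gaps.

    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    score = _subst(scheme)
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            H[i][j] = max(0.0, H[i - 1][j - 1] + score(ai, seq_b[j - 1]), E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def average_precision_reference(scores, labels) -> float:
    """Brute-force PR-point enumeration: step area over distinct thresholds."""
    items = sorted(zip(scores, labels), key=lambda t: -t[0])
    thresholds = sorted({s for s, _ in items}, reverse=True)
    n_pos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    for thr in thresholds:
        taken = [(s, y) for s, y in items if s >= thr]
        tp = sum(y for _, y in taken)
        precision = tp / len(taken)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
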
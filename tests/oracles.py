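"""Independent brute-force oracles used to verify the package's statistics.

Each oracle is deliberately written with a different algorithmic route than
the implementation it checks: per-sample loops instead of vectorized masks,
direct enumeration of contingency tables instead of closed-form tails, and
explicit permutation enumeration for the trend test.
"""

from itertools import combinations
from math import comb, sqrt


def des_bruteforce(cn_row, expr_row, loss=1.7, gain=2.3, k=1.0,
                   min_cna_fraction=0.10, min_neutral=5):
    """Dosage effect score by enumerating samples one at a time.

    Returns (des, cna_count, concordant_count); des is None when undefined.
    """
    n = len(cn_row)
    neutral_vals, gains, losses = [], [], []
    for cn, ex in zip(cn_row, expr_row):
        if cn is None or cn != cn:  # missing
            continue
        if cn < loss:
            losses.append(ex)
        elif cn > gain:
            gains.append(ex)
        else:
            neutral_vals.append(ex)
    cna = len(gains) + len(losses)
    if cna <= min_cna_fraction * n or len(neutral_vals) < min_neutral:
        return None, cna, None
    mean = sum(neutral_vals) / len(neutral_vals)
    var = sum((v - mean) ** 2 for v in neutral_vals) / (len(neutral_vals) - 1)
    sd = sqrt(var)
    if sd == 0:
        return None, cna, None
    concordant = sum(1 for v in gains if v > mean + k * sd)
    concordant += sum(1 for v in losses if v < mean - k * sd)
    return concordant / cna, cna, concordant


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of every
    table with the observed margins whose probability is <= the observed
    table's (probability-mass criterion)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = comb(r1, x) * comb(r2, c1 - x) / denom
        if p_x <= p_obs * (1 + 1e-9):
            total += p_x
    return min(total, 1.0)


def trend_permutation_p(table, scores=None):
    """Exact conditional trend p by enumerating which of the N subjects fall
    in row 1 (feasible for small totals).

    P(|T - E[T]| >= |t_obs - E[T]|) where T = sum of scores of the row-1
    subjects, conditioning on all margins.
    """
    table = [list(map(int, row)) for row in table]
    k = len(table[0])
    scores = list(scores) if scores is not None else list(range(1, k + 1))
    subject_scores = []
    for j in range(k):
        subject_scores.extend([scores[j]] * (table[0][j] + table[1][j]))
    r1 = sum(table[0])
    n = len(subject_scores)
    t_obs = sum(scores[j] * table[0][j] for j in range(k))
    col = [table[0][j] + table[1][j] for j in range(k)]
    e_t = r1 / n * sum(scores[j] * col[j] for j in range(k))
    hits = 0
    total = 0
    threshold = abs(t_obs - e_t) - 1e-9
    for chosen in combinations(range(n), r1):
        t = sum(subject_scores[i] for i in chosen)
        total += 1
        if abs(t - e_t) >= threshold:
            hits += 1
    return hits / total
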
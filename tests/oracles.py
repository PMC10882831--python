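"""Independent brute-force oracles for the core operations.

These are deliberately naive (pure-Python loops, Counters, exhaustive
scans) and share no code with the implementations they check.
"""

from __future__ import annotations

from collections import Counter


def vote_consensus_oracle(
    seqs: list[str], min_agreement: float
) -> str:
    """Column-wise majority vote with tie masking, on equal-extent reads."""
    k = len(seqs)
    out = []
    for col in zip(*seqs):
        counts = Counter(col)
        (top_base, top_n), *rest = counts.most_common()
        runner = rest[0][1] if rest else 0
        if top_n >= min_agreement * k and top_n > runner:
            out.append(top_base)
        else:
            out.append("N")
    return "".join(out)


def tally_calls_oracle(molecules, reference):
    """Exhaustive per-cell per-position tally of consensus-vs-reference.

    ``molecules`` are (cell, tx, start, consensus_string) tuples. Returns
    {(cell, tx, pos, alt): (n_mut, n_wt)} ignoring masked N bases.
    """
    out = {}
    for cell, tx, start, seq in molecules:
        ref = reference[tx]
        for i, base in enumerate(seq):
            pos = start + i
            if base == "N" or base == ref[pos]:
                continue
            key = (cell, tx, pos, base)
            if key in out:
                continue
            n_mut = sum(
                1
                for c2, t2, s2, q2 in molecules
                if c2 == cell
                and t2 == tx
                and s2 <= pos < s2 + len(q2)
                and q2[pos - s2] == base
            )
            n_wt = sum(
                1
                for c2, t2, s2, q2 in molecules
                if c2 == cell
                and t2 == tx
                and s2 <= pos < s2 + len(q2)
                and q2[pos - s2] == ref[pos]
            )
            out[key] = (n_mut, n_wt)
    return out


def period_oracle(
    seq: str,
    min_period: int,
    max_period: int,
    max_mismatch_frac: float = 0.1,
    min_repeats: int = 3,
):
    """Exhaustive scan over all candidate periods; smallest best p wins."""
    L = len(seq)
    best, best_frac = None, None
    for p in range(min_period, min(max_period, L - 1) + 1):
        if L // p < min_repeats:
            continue
        mism = sum(1 for i in range(L - p) if seq[i] != seq[i + p])
        frac = mism / (L - p)
        if frac > max_mismatch_frac:
            continue
        if best_frac is None or frac < best_frac:
            best, best_frac = p, frac
    return best


def fold_oracle(seq: str, quals: str, period: int):
    """Column-wise quality-weighted vote over tandem repeats.

    Returns (consensus string with N masks, [(n_agree, n_total)]). The
    winner needs summed quality >= 2x the runner-up; ties mask.
    """
    L = len(seq)
    cons, support = [], []
    for j in range(period):
        entries = [(seq[i], ord(quals[i]) - 33) for i in range(j, L, period)]
        qsum: Counter = Counter()
        counts: Counter = Counter()
        for b, q in entries:
            qsum[b] += q
            counts[b] += 1
        ordered = sorted("ACGT", key=lambda b: qsum[b])
        win, run = ordered[-1], ordered[-2]
        if qsum[win] < 2 * qsum[run]:
            cons.append("N")
        else:
            cons.append(win)
        support.append((counts[win], len(entries)))
    return "".join(cons), support


def cirseq_column_distribution(e: float, n_copies: int = 3):
    """Enumerate per-column outcomes of folding with equal qualities.

    Each copy reads the true base correctly w.p. 1-e or as one of the 3
    other bases w.p. e/3 each. Returns (P(consensus wrong), P(masked))
    by summing over all 4^n outcomes with the 2x-quality mask rule.
    """
    from itertools import product

    p_wrong = 0.0
    p_masked = 0.0
    outcomes = ["R", "X", "Y", "Z"]  # true base and the three alts
    probs = {"R": 1 - e, "X": e / 3, "Y": e / 3, "Z": e / 3}
    for combo in product(outcomes, repeat=n_copies):
        p = 1.0
        for c in combo:
            p *= probs[c]
        counts = Counter(combo)
        ordered = sorted(outcomes, key=lambda b: counts[b])
        win, run = ordered[-1], ordered[-2]
        if counts[win] < 2 * counts[run]:
            p_masked += p
        elif win != "R":
            p_wrong += p
    return p_wrong, p_masked


def student_t_oracle(a, b):
    """Textbook pooled-variance unpaired two-tailed t-test."""
    import math

    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
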
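"""Disease-resistance scoring from pathogen colonisation-class tables.

Leaves of each plant line are assigned to ordinal colonisation classes
(I: no hyphal colonisation ... IV: extensive colonisation with conidiophores
and oospores).  Differences in class distributions between lines are tested
with the exact conditional (Fisher) test for 2xK tables: the p-value is the
total probability, under fixed margins, of all tables whose point probability
does not exceed the observed one.  All-versus-all line comparisons are
BH-adjusted and summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dmp import adjust_fdr

CLASS_NAMES = ("I", "II", "III", "IV")
_MAX_TABLES = 50_000_000


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_rxc(table) -> float:
    """Exact conditional p for a 2xK (or Kx2) contingency table.

    Enumerates all tables with the observed margins (vectorised over the free
    first-row entries) and sums the probability of tables no more probable
    than the observed one.  Zero-margin rows/columns are dropped with a
    warning.  Complexity is the product of the free-entry ranges; the leaf
    counts of a colonisation assay (a few hundred per line) stay far below the
    guard limit.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if 2 not in t.shape:
        raise ValueError("one dimension must have size 2")
    if t.shape[0] != 2:
        t = t.T
    col_ok = t.sum(axis=0) > 0
    if not col_ok.all():
        warnings.warn("dropping zero-margin columns")
        t = t[:, col_ok]
    if (t.sum(axis=1) == 0).any():
        warnings.warn("a zero-margin row makes the test degenerate; p = 1")
        return 1.0
    if t.shape[1] < 2:
        return 1.0
    r1 = int(t[0].sum())
    c = t.sum(axis=0)
    n = int(t.sum())

    ranges = [np.arange(max(0, r1 - int(n - cj)), min(r1, int(cj)) + 1)
              for cj in c[:-1]]
    size = int(np.prod([len(r) for r in ranges]))
    if size > _MAX_TABLES:
        raise ValueError(f"enumeration too large ({size} tables)")
    # broadcast the free entries a_1..a_{K-1}; the last column is determined
    shape = [len(r) for r in ranges]
    total = np.zeros(shape)
    logp = np.zeros(shape)
    for j, r in enumerate(ranges):
        view = [None] * len(ranges)
        view[j] = slice(None)
        total = total + r[tuple(view)]
        logp = logp + _log_comb(c[j], r)[tuple(view)]
    a_last = r1 - total
    valid = (a_last >= 0) & (a_last <= c[-1])
    logp = logp + np.where(valid, _log_comb(c[-1], np.clip(a_last, 0, c[-1])), -np.inf)
    logp = logp - _log_comb(n, r1)
    log_obs = float(np.sum(_log_comb(c, t[0])) - _log_comb(n, r1))
    mask = valid & (logp <= log_obs + 1e-7)
    return float(min(np.exp(logp[mask]).sum(), 1.0))


def all_versus_all(tables: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Pairwise exact tests between all lines, BH-adjusted, with letter groups.

    ``tables``: lines as rows, colonisation classes as columns.  Lines sharing
    a letter are not significantly different at the adjusted alpha.
    """
    lines = list(tables.index)
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    pairs = list(itertools.combinations(lines, 2))
    pvals = [fisher_exact_rxc(tables.loc[[a, b]].to_numpy()) for a, b in pairs]
    qvals = adjust_fdr(pvals)
    res = pd.DataFrame({
        "line_a": [a for a, _ in pairs],
        "line_b": [b for _, b in pairs],
        "p": pvals,
        "q": qvals,
        "significant": qvals <= alpha,
    })
    letters = compact_letter_display(lines, {
        (r.line_a, r.line_b): bool(r.significant) for r in res.itertuples()
    })
    return res, letters


def compact_letter_display(lines, significant: dict) -> dict:
    """Greedy letter grouping: a line joins a group only if it is not
    significantly different from every current member; lines may carry several
    letters.  The paper-style display shows letters, not the algorithm, so the
    greedy insertion order (input order) is the documented convention."""
    def differs(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    groups: list[list] = []
    seen: list = []
    for ln in lines:
        placed = False
        for g in groups:
            if all(not differs(ln, m) for m in g):
                g.append(ln)
                placed = True
        if not placed:
            g = [ln]
            # pull in earlier lines compatible with the whole new group
            for m in seen:
                if all(not differs(m, x) for x in g):
                    g.append(m)
            groups.append(g)
        seen.append(ln)
    # drop groups fully contained in another
    keep = []
    for i, g in enumerate(groups):
        if not any(set(g) < set(h) for j, h in enumerate(groups) if j != i):
            keep.append(g)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {ln: "" for ln in lines}
    for letter, g in zip(alphabet, keep):
        for ln in g:
            out[ln] += letter
    return out


def simulate_colonisation(
    class_probs: dict,
    n_leaves: dict | int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Multinomial colonisation-class tables, one row per line.

    ``class_probs``: line -> probability vector over classes (must sum to 1);
    ``n_leaves``: leaves scored per line (int applies to all lines).
    """
    rows = {}
    for line, probs in class_probs.items():
        p = np.asarray(probs, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"line {line}: class probabilities must sum to 1")
        n = n_leaves[line] if isinstance(n_leaves, dict) else int(n_leaves)
        rows[line] = rng.multinomial(n, p) if n > 0 else np.zeros(len(p), dtype=int)
    k = len(next(iter(rows.values())))
    cols = list(CLASS_NAMES[:k]) if k <= 4 else [str(i + 1) for i in range(k)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
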
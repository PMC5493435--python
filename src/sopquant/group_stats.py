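"""Group-comparison tests: exact Mann-Whitney and the Freeman-Halton test.

Two procedures cover every group comparison in the pipeline, implemented
from first principles:

* :func:`mann_whitney` — the rank-sum test for two independent samples of a
  continuous score (polarization coefficients, segregation ratios, ...).
  For small untied samples (n_a + n_b <= 16) the p-value is exact, by full
  enumeration of all C(n_a + n_b, n_a) group labelings; otherwise the
  normal approximation with tie and continuity corrections is used. The
  two-sided exact p is 2 * min(tail probabilities) capped at 1.

* :func:`freeman_halton_exact` — the Freeman-Halton extension of Fisher's
  exact test to r x c tables of defect-category counts per genotype. The
  p-value sums the multivariate hypergeometric probabilities, conditional on
  both margins, of every table whose probability is at or below the observed
  table's ("as or more extreme" by probability ordering). The fixed-margin
  table space is enumerated when small enough, otherwise a seeded
  permutation Monte-Carlo estimates the same tail.

All hypergeometric weights are computed with log-factorials (lgamma), so
tables with totals in the hundreds do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, lgamma

import numpy as np

__all__ = [
    "ContingencyTable",
    "TestResult",
    "mann_whitney",
    "freeman_halton_exact",
    "compare_genotypes",
]

#: relative tolerance on probability ties in the "as or more extreme" comparison
_PROB_RTOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable:
    """r x c nonnegative integer counts: genotypes (rows) x defect categories."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if np.any(counts != np.floor(counts)) or np.any(counts < 0):
                raise ValueError("counts must be nonnegative integers")
            counts = counts.astype(int)
        if counts.sum() < 1:
            raise ValueError("grand total must be >= 1")
        object.__setattr__(self, "counts", counts.astype(int))
        r, c = counts.shape
        if not self.row_labels:
            object.__setattr__(self, "row_labels", [f"row{i}" for i in range(r)])
        if not self.col_labels:
            object.__setattr__(self, "col_labels", [f"col{j}" for j in range(c)])
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match table shape")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation" | "monte-carlo"
    n_tables_or_perms: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney(sample_a, sample_b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    The reported statistic is U = min(U_a, U_b) from midranks. One-sided
    alternatives are stated for sample_a: "less" means sample_a tends to
    smaller values than sample_b.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)  # #{a > b} + ties/2
    u_b = na * nb - u_a
    u_min = min(u_a, u_b)
    has_ties = np.unique(combined).size < combined.size

    if na + nb <= 16 and not has_ties:
        # exact: U_a over all C(na+nb, na) equally likely rank assignments
        n = na + nb
        u_values = np.fromiter(
            (sum(pos) - na * (na - 1) // 2 for pos in combinations(range(n), na)),
            dtype=float,
            count=comb(n, na),
        )
        total = u_values.size
        p_le = np.count_nonzero(u_values <= u_a + 1e-9) / total
        p_ge = np.count_nonzero(u_values >= u_a - 1e-9) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=u_min, p_value=p, method="exact", n_tables_or_perms=total)

    # normal approximation with tie correction and continuity correction
    n = na + nb
    mu = na * nb / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # every observation identical: no evidence either way
        return TestResult(statistic=u_min, p_value=1.0, method="normal-approximation", n_tables_or_perms=0)
    sd = np.sqrt(var)
    from scipy.stats import norm

    if alternative == "less":
        z = (u_a - mu + 0.5) / sd
        p = float(norm.cdf(z))
    elif alternative == "greater":
        z = (u_a - mu - 0.5) / sd
        p = float(norm.sf(z))
    else:
        z = (u_a - mu - np.sign(u_a - mu) * 0.5) / sd if u_a != mu else 0.0
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(statistic=u_min, p_value=p, method="normal-approximation", n_tables_or_perms=0)


# ---------------------------------------------------------------------------
# Freeman-Halton exact test
# ---------------------------------------------------------------------------

def _log_table_weight(cells: np.ndarray) -> float:
    """-sum(lgamma(n_ij + 1)); margins contribute a constant dropped here."""
    return -float(sum(lgamma(x + 1.0) for x in cells.ravel()))


def _enumerate_tables(row_sums, col_sums):
    """Yield the cell arrays of every table with the given margins.

    Recursive margin-constrained fill, row by row; the last row is forced.
    """
    r = len(row_sums)
    c = len(col_sums)
    table = np.zeros((r, c), dtype=int)
    col_rem = np.array(col_sums, dtype=int)

    def fill_row(i: int):
        if i == r - 1:
            if np.all(col_rem >= 0) and col_rem.sum() == row_sums[i]:
                table[i] = col_rem
                yield table
            return

        def fill_cell(j: int, remaining: int):
            if j == c - 1:
                if 0 <= remaining <= col_rem[j]:
                    table[i, j] = remaining
                    col_rem[j] -= remaining
                    yield from fill_row(i + 1)
                    col_rem[j] += remaining
                return
            hi = min(remaining, col_rem[j])
            for v in range(hi + 1):
                table[i, j] = v
                col_rem[j] -= v
                yield from fill_cell(j + 1, remaining - v)
                col_rem[j] += v

        yield from fill_cell(0, int(row_sums[i]))

    yield from fill_row(0)


def _composition_bound(row_sums, c: int) -> int:
    """Upper bound on the fixed-margin table count (column bounds ignored)."""
    bound = 1
    for rs in row_sums[:-1]:  # last row is forced
        bound *= comb(int(rs) + c - 1, c - 1)
        if bound > 10**12:
            return bound
    return bound


def freeman_halton_exact(
    table: ContingencyTable,
    monte_carlo_threshold: int = 5_000_000,
    seed: int | None = None,
    n_monte_carlo: int = 20_000,
) -> TestResult:
    """Freeman-Halton (Fisher exact, r x c) test of independence.

    p is the total conditional probability of all fixed-margin tables at
    least as improbable as the observed one. Enumeration runs when the
    (bounded) table-space size is at most ``monte_carlo_threshold``;
    otherwise a seeded permutation Monte-Carlo with ``n_monte_carlo`` draws
    estimates the same tail, with the add-one correction (1 + extreme) /
    (1 + draws).

    A table with an all-zero row or column is degenerate: the margins admit
    no alternative arrangement evidence, so p = 1.0 is returned with the
    ``degenerate`` flag set rather than raising.
    """
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)

    obs_logw = _log_table_weight(counts)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        return TestResult(
            statistic=obs_logw, p_value=1.0, method="exact", n_tables_or_perms=1, degenerate=True
        )

    n = int(counts.sum())
    log_margin_const = (
        sum(lgamma(x + 1.0) for x in row_sums)
        + sum(lgamma(x + 1.0) for x in col_sums)
        - lgamma(n + 1.0)
    )
    # inclusion threshold: prob <= p_obs within relative tolerance
    thresh = obs_logw + np.log1p(_PROB_RTOL)

    if _composition_bound(row_sums, counts.shape[1]) <= monte_carlo_threshold:
        logps = []
        n_tables = 0
        for t in _enumerate_tables(row_sums, col_sums):
            n_tables += 1
            lw = _log_table_weight(t)
            if lw <= thresh:
                logps.append(log_margin_const + lw)
        if logps:
            m = max(logps)
            p = float(np.exp(m) * np.sum(np.exp(np.array(logps) - m)))
        else:  # at minimum the observed table itself qualifies
            p = float(np.exp(log_margin_const + obs_logw))
        p = min(1.0, p)
        return TestResult(statistic=obs_logw, p_value=p, method="exact", n_tables_or_perms=n_tables)

    # Monte-Carlo over margin-preserving tables: permute row labels of the
    # n individual observations, bin by column blocks
    rng = np.random.default_rng(seed)
    row_of_obs = np.repeat(np.arange(counts.shape[0]), row_sums)
    col_edges = np.concatenate([[0], np.cumsum(col_sums)])
    extreme = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(row_of_obs)
        t = np.column_stack(
            [
                np.bincount(perm[col_edges[j] : col_edges[j + 1]], minlength=counts.shape[0])
                for j in range(counts.shape[1])
            ]
        )
        if _log_table_weight(t) <= thresh:
            extreme += 1
    p = (1.0 + extreme) / (1.0 + n_monte_carlo)
    return TestResult(
        statistic=obs_logw, p_value=float(p), method="monte-carlo", n_tables_or_perms=n_monte_carlo
    )


def compare_genotypes(
    defect_records: dict,
    categories=None,
    monte_carlo_threshold: int = 5_000_000,
    seed: int | None = None,
) -> tuple[ContingencyTable, TestResult]:
    """Tabulate per-individual defect categories per genotype and test.

    ``defect_records`` maps genotype name to the list of category labels
    observed (one per scored wing/fly). When ``categories`` is given,
    unknown labels raise; otherwise columns are the sorted union of labels.
    """
    if len(defect_records) < 2:
        raise ValueError("need at least 2 genotypes")
    for g, recs in defect_records.items():
        if len(recs) < 1:
            raise ValueError(f"genotype {g!r} has no records")
    if categories is None:
        categories = sorted({c for recs in defect_records.values() for c in recs})
    else:
        categories = list(categories)
        known = set(categories)
        for g, recs in defect_records.items():
            for c in recs:
                if c not in known:
                    raise ValueError(f"unknown defect category {c!r} in genotype {g!r}")
    cat_index = {c: j for j, c in enumerate(categories)}
    genotypes = list(defect_records)
    counts = np.zeros((len(genotypes), len(categories)), dtype=int)
    for i, g in enumerate(genotypes):
        for c in defect_records[g]:
            counts[i, cat_index[c]] += 1
    table = ContingencyTable(counts=counts, row_labels=genotypes, col_labels=categories)
    result = freeman_halton_exact(table, monte_carlo_threshold=monte_carlo_threshold, seed=seed)
    return table, result
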
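"""Categorical-response framework: Fisher's exact test on genotype-by-
outcome contingency tables, overall and per stratum.

Three p-value routes share one two-sided convention — the probability of
all margin-fixed tables whose null probability is at most the observed
table's (relative tolerance 1 + 1e-7):

* ``fisher_exact_2x2`` — the hypergeometric 2x2 special case, with a
  sample odds ratio and a log-odds normal CI (Haldane–Anscombe 0.5
  correction only when a zero cell is present);
* ``fisher_exact_enumerate`` — full recursion over all r x c tables with
  the observed margins (multivariate hypergeometric null);
* ``fisher_montecarlo`` — seeded sequential sampling of tables with both
  margins fixed (row-wise multivariate hypergeometric draws, the
  classical fill-by-row construction), with the add-one estimator
  p = (1 + hits) / (B + 1) so a simulated p is never exactly zero.

The Monte-Carlo statistic is the table's null probability itself, so the
simulated p targets exactly the enumerated p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

from .phen_data import (GENOTYPE, LIFESTAGE, SEX, ModelSpec, PhenDataset,
                        ValidationError)

P_REL_TOL = 1e-7          # two-sided "at most observed" relative tolerance
ENUM_BOUND = 1_000_000    # max number of enumerated tables


class DegenerateTableError(ValueError):
    """The table has a zero margin and cannot be tested."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]            # reference genotype first
    counts: np.ndarray               # shape (rows, cols), non-negative ints
    stratum: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict[str, Any]:
        return {"row_labels": list(self.row_labels),
                "col_labels": list(self.col_labels),
                "counts": self.counts.tolist(),
                "stratum": self.stratum}


@dataclass
class FisherOutcome:
    p_value: float
    method: str                      # exact_2x2 | exact_enumeration | monte_carlo
    effect_size_percent: float
    mc_draws: int | None = None
    mc_std_error: float | None = None
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict[str, Any]:
        return {"p_value": self.p_value, "method": self.method,
                "mc_draws": self.mc_draws, "mc_std_error": self.mc_std_error,
                "odds_ratio": self.odds_ratio,
                "or_ci": list(self.or_ci) if self.or_ci else None,
                "effect_size_percent": self.effect_size_percent}


@dataclass
class ContingencyResult:
    strata: dict[str, dict[str, Any]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def genotype_p(self) -> float | None:
        main = self.strata.get("all")
        if main is None or main.get("outcome") is None:
            return None
        return main["outcome"]["p_value"]

    def to_dict(self) -> dict[str, Any]:
        return {"framework": "FisherExact",
                "strata": self.strata, "skipped": dict(self.skipped),
                "genotype_p": self.genotype_p}


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_contingency(ds: PhenDataset,
                      stratum: dict[str, str] | None = None,
                      label: str = "all") -> ContingencyTable | None:
    """Cross-tabulate response x genotype within a stratum.

    ``stratum`` maps column name -> required level (None for the whole
    dataset).  Response categories with zero total count are dropped;
    the reference genotype column comes first, response levels keep
    first-appearance order.  An empty stratum yields ``None`` (recorded
    by the caller), not an exception.
    """
    df = ds.data
    if stratum:
        for col, val in stratum.items():
            if col not in df.columns:
                return None
            df = df[df[col].astype(str) == str(val)]
    df = df[[ds.spec.response, GENOTYPE]].dropna()
    if len(df) == 0:
        return None
    resp = df[ds.spec.response].astype(str)
    geno = df[GENOTYPE].astype(str)
    row_levels = list(dict.fromkeys(resp))
    ref = ds.reference_genotype
    col_levels = ([ref] if ref in set(geno) else []) + [
        g for g in dict.fromkeys(geno) if g != ref]
    counts = np.zeros((len(row_levels), len(col_levels)), dtype=np.int64)
    ri = {r: i for i, r in enumerate(row_levels)}
    ci = {c: j for j, c in enumerate(col_levels)}
    for r, c in zip(resp, geno):
        counts[ri[r], ci[c]] += 1
    keep = counts.sum(axis=1) > 0
    return ContingencyTable(row_labels=[r for r, k in zip(row_levels, keep) if k],
                            col_labels=col_levels,
                            counts=counts[keep], stratum=label)


def _check_margins(t: ContingencyTable) -> None:
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise DegenerateTableError("degenerate table: zero margin")


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

_LGAMMA_CACHE: dict[int, float] = {}


def _lfact(n: int) -> float:
    v = _LGAMMA_CACHE.get(n)
    if v is None:
        v = lgamma(n + 1)
        _LGAMMA_CACHE[n] = v
    return v


def table_log_prob(counts: np.ndarray, row_margins: np.ndarray,
                   col_margins: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a margin-fixed table."""
    n = int(row_margins.sum())
    lp = (sum(_lfact(int(r)) for r in row_margins)
          + sum(_lfact(int(c)) for c in col_margins)
          - _lfact(n))
    lp -= sum(_lfact(int(x)) for x in counts.ravel())
    return lp


def categorical_effect_size(t: ContingencyTable) -> float:
    """Maximum percentage change: 100 x the largest absolute difference
    between a mutant column's within-genotype category proportion and the
    reference column's, over all categories and mutant columns."""
    if t.counts.shape[1] < 2:
        raise ValidationError("effect size needs at least two genotype columns")
    cm = t.col_margins
    if (cm[:1] == 0).any() or (cm[1:] == 0).all():
        raise DegenerateTableError("degenerate table: empty genotype column")
    props = t.counts / np.where(cm == 0, 1, cm)[None, :]
    diffs = np.abs(props[:, 1:] - props[:, :1])
    usable = cm[1:] > 0
    if not usable.any():
        raise DegenerateTableError("degenerate table: empty genotype column")
    return float(100.0 * diffs[:, usable].max())


def _or_and_ci(t: ContingencyTable, alpha: float) -> tuple[float, tuple[float, float]]:
    from scipy import stats as sps
    a, b = float(t.counts[0, 0]), float(t.counts[0, 1])
    c, d = float(t.counts[1, 0]), float(t.counts[1, 1])
    if min(a, b, c, d) == 0.0:  # Haldane–Anscombe correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(odds) - z * se), np.exp(np.log(odds) + z * se)
    return float(odds), (float(lo), float(hi))


def fisher_exact_2x2(t: ContingencyTable, alpha: float = 0.05) -> FisherOutcome:
    """Two-sided exact test of a 2x2 table via the hypergeometric null."""
    if t.counts.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    _check_margins(t)
    from scipy.stats import hypergeom
    r1, _ = (int(x) for x in t.row_margins)
    c1, c2 = (int(x) for x in t.col_margins)
    n = t.total
    # cell (0,0) ranges over the support given margins
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(int(t.counts[0, 0]), n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + P_REL_TOL)].sum())
    p = min(1.0, p)
    odds, ci = _or_and_ci(t, alpha)
    return FisherOutcome(p_value=p, method="exact_2x2",
                         effect_size_percent=categorical_effect_size(t),
                         odds_ratio=odds, or_ci=ci)


def iter_margin_tables(row_margins: Sequence[int], col_margins: Sequence[int],
                       bound: int = ENUM_BOUND) -> Iterator[np.ndarray]:
    """Yield every non-negative integer table with the given margins.

    Rows are filled recursively; the last row is forced.  Raises when
    more than ``bound`` tables would be produced.
    """
    rm = [int(x) for x in row_margins]
    cm = np.asarray([int(x) for x in col_margins])
    r, c = len(rm), len(cm)
    count = 0

    def row_fills(total: int, caps: np.ndarray) -> Iterator[tuple[int, ...]]:
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        head_max = min(total, int(caps[0]))
        # feasibility: the rest must be able to absorb the remainder
        head_min = max(0, total - int(caps[1:].sum()))
        for v in range(head_min, head_max + 1):
            for rest in row_fills(total - v, caps[1:]):
                yield (v,) + rest

    def rec(i: int, remaining: np.ndarray, acc: list[tuple[int, ...]]
            ) -> Iterator[np.ndarray]:
        nonlocal count
        if i == r - 1:
            if (remaining >= 0).all() and remaining.sum() == rm[i]:
                count += 1
                if count > bound:
                    raise OverflowError(
                        f"enumeration bound {bound} exceeded; use monte_carlo")
                yield np.array(acc + [tuple(int(x) for x in remaining)],
                               dtype=np.int64)
            return
        for fill in row_fills(rm[i], remaining):
            yield from rec(i + 1, remaining - np.asarray(fill), acc + [fill])

    yield from rec(0, cm.copy(), [])


def fisher_exact_enumerate(t: ContingencyTable,
                           bound: int = ENUM_BOUND) -> FisherOutcome:
    """Exact two-sided p for an r x c table by full enumeration of the
    margin-fixed table distribution."""
    _check_margins(t)
    rm, cm = t.row_margins, t.col_margins
    lp_obs = table_log_prob(t.counts, rm, cm)
    thresh = lp_obs + np.log1p(P_REL_TOL)
    p = 0.0
    n_tables = n_included = 0
    for tab in iter_margin_tables(rm, cm, bound=bound):
        n_tables += 1
        lp = table_log_prob(tab, rm, cm)
        if lp <= thresh:
            n_included += 1
            p += np.exp(lp)
    if n_included == n_tables:
        p = 1.0  # every table as extreme as observed: p is exactly one
    return FisherOutcome(p_value=float(min(1.0, p)), method="exact_enumeration",
                         effect_size_percent=categorical_effect_size(t))


def enumerate_distribution(t: ContingencyTable,
                           bound: int = ENUM_BOUND) -> np.ndarray:
    """Null probabilities of all margin-fixed tables (diagnostic; sums to 1)."""
    rm, cm = t.row_margins, t.col_margins
    return np.array([np.exp(table_log_prob(tab, rm, cm))
                     for tab in iter_margin_tables(rm, cm, bound=bound)])


def sample_margin_table(rng: np.random.Generator, row_margins: np.ndarray,
                        col_margins: np.ndarray) -> np.ndarray:
    """One draw from the margin-fixed null: fill rows sequentially with
    multivariate hypergeometric draws against the remaining column margins."""
    remaining = col_margins.astype(np.int64).copy()
    rows = []
    for r in row_margins[:-1]:
        fill = rng.multivariate_hypergeometric(remaining, int(r))
        rows.append(fill)
        remaining -= fill
    rows.append(remaining.copy())
    return np.asarray(rows, dtype=np.int64)


def fisher_montecarlo(t: ContingencyTable, draws: int = 10000,
                      seed: int | None = None) -> FisherOutcome:
    """Monte-Carlo two-sided p over ``draws`` margin-fixed simulated tables."""
    if draws < 100:
        raise ValidationError("too few draws: Monte-Carlo needs at least 100")
    _check_margins(t)
    rng = np.random.default_rng(seed)
    rm, cm = t.row_margins, t.col_margins
    thresh = table_log_prob(t.counts, rm, cm) + np.log1p(P_REL_TOL)
    hits = 0
    for _ in range(draws):
        tab = sample_margin_table(rng, rm, cm)
        if table_log_prob(tab, rm, cm) <= thresh:
            hits += 1
    p = (1.0 + hits) / (draws + 1.0)
    se = float(np.sqrt(p * (1.0 - p) / draws))
    return FisherOutcome(p_value=float(p), method="monte_carlo",
                         mc_draws=draws, mc_std_error=se,
                         effect_size_percent=categorical_effect_size(t))


def test_table(t: ContingencyTable, mc_draws: int = 10000,
               seed: int | None = None,
               enum_bound: int = ENUM_BOUND) -> FisherOutcome:
    """Dispatch: 2x2 exact, else enumeration within bound, else Monte-Carlo."""
    if t.counts.shape == (2, 2):
        return fisher_exact_2x2(t)
    try:
        return fisher_exact_enumerate(t, bound=enum_bound)
    except OverflowError:
        return fisher_montecarlo(t, draws=mc_draws, seed=seed)


# pytest must not collect the dispatcher as a test function
test_table.__test__ = False  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# stratified analysis
# ---------------------------------------------------------------------------

def _strata_descriptors(ds: PhenDataset) -> list[tuple[str, dict[str, str] | None]]:
    out: list[tuple[str, dict[str, str] | None]] = [("all", None)]
    sexes = (sorted(ds.data[SEX].dropna().astype(str).unique())
             if SEX in ds.data.columns else [])
    stages = (sorted(ds.data[LIFESTAGE].dropna().astype(str).unique())
              if LIFESTAGE in ds.data.columns else [])
    if len(sexes) > 1:
        out += [(s, {SEX: s}) for s in sexes]
    if len(stages) > 1:
        out += [(l, {LIFESTAGE: l}) for l in stages]
        if len(sexes) > 1:
            out += [(f"{s}.{l}", {SEX: s, LIFESTAGE: l})
                    for s in sexes for l in stages]
    return out


def analyze_categorical(ds: PhenDataset,
                        spec: ModelSpec | None = None) -> ContingencyResult:
    """Build and test tables for the whole dataset, each sex, each
    lifestage and the sex-by-lifestage combinations present in the data."""
    spec = spec if spec is not None else ds.spec
    result = ContingencyResult()
    for label, desc in _strata_descriptors(ds):
        table = build_contingency(ds, desc, label)
        if table is None:
            result.skipped[label] = "empty stratum"
            continue
        entry: dict[str, Any] = {"table": table.to_dict()}
        if table.counts.shape[0] < 2 or table.counts.shape[1] < 2:
            entry["outcome"] = None
            entry["not_testable"] = "table reduced below 2x2"
        else:
            try:
                outcome = test_table(table, mc_draws=spec.mc_draws,
                                     seed=spec.seed)
                entry["outcome"] = outcome.to_dict()
            except DegenerateTableError as exc:
                entry["outcome"] = None
                entry["not_testable"] = str(exc)
        result.strata[label] = entry
    return result
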
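"""Reference Range Plus: discretize a continuous response against the
control distribution and test directional collapsed tables exactly.

The idea: a phenotype is called when mutant animals fall outside the
natural variation of the controls.  A central coverage band of the
control distribution (default 95%) defines Low / Normal / High classes
(band boundaries are inclusive in Normal, the conservative direction);
the genotype-by-class counts are collapsed into two 2x2 tables —
Low+Normal vs High, and Low vs Normal+High — each tested with Fisher's
exact test.

Repeated measurement values can put an empirical quantile inside a tie
mass; the threshold is then moved outward to the first strictly distinct
order statistic, which can only widen the Normal band (the achieved
coverage ``q_effective`` is recomputed and never falls below ``q``).
Thresholds always come from the controls of the same stratum: the main
effect uses all controls, sex-specific tests use sex-matched controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .fisher import (ContingencyTable, DegenerateTableError, FisherOutcome,
                     categorical_effect_size, fisher_exact_2x2)
from .phen_data import GENOTYPE, SEX, ModelSpec, PhenDataset, ValidationError

CLASSES = ("Low", "Normal", "High")


@dataclass
class RRThresholds:
    q: float
    lower: float
    upper: float
    q_effective: float
    adjusted: bool
    stratum: str = "all"
    n_controls: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {"q": self.q, "lower": self.lower, "upper": self.upper,
                "q_effective": self.q_effective, "adjusted": self.adjusted,
                "stratum": self.stratum, "n_controls": self.n_controls}


def control_thresholds(controls: np.ndarray | pd.Series, q: float = 0.95,
                       stratum: str = "all") -> RRThresholds:
    """Empirical central-coverage band of the control distribution.

    ``lower``/``upper`` are the linear-interpolation empirical quantiles
    at (1-q)/2 and 1-(1-q)/2.  If more controls fall strictly outside a
    threshold than that tail's budget allows (a tie mass straddling the
    quantile position), the threshold moves outward to the nearest
    strictly distinct order statistic.  A threshold landing exactly on a
    tied value is also flagged adjusted — the band absorbed the tie mass.
    """
    x = np.asarray(pd.Series(controls).dropna(), dtype=float)
    if x.size < 2:
        raise ValidationError("reference distribution too small: need >= 2 controls")
    if not (0.5 < q < 1.0):
        raise ValidationError("q must lie strictly in (0.5, 1)")
    tail = (1.0 - q) / 2.0
    lower, upper = (float(v) for v in np.quantile(x, [tail, 1.0 - tail]))
    n = x.size
    budget = n * tail
    uniq = np.unique(x)
    adjusted = False
    if np.sum(x < lower) > budget:
        below = uniq[uniq <= lower]
        # walk outward until the strict-Low tail fits its budget
        for v in below[::-1]:
            if np.sum(x < v) <= budget:
                lower = float(v)
                break
        else:
            lower = float(uniq[0])
        adjusted = True
    if np.sum(x > upper) > budget:
        above = uniq[uniq >= upper]
        for v in above:
            if np.sum(x > v) <= budget:
                upper = float(v)
                break
        else:
            upper = float(uniq[-1])
        adjusted = True
    for th in (lower, upper):
        if np.sum(x == th) > 1:
            adjusted = True
    q_effective = float(np.mean((x >= lower) & (x <= upper)))
    return RRThresholds(q=q, lower=lower, upper=upper,
                        q_effective=q_effective, adjusted=adjusted,
                        stratum=stratum, n_controls=int(n))


def discretize_response(values: np.ndarray | pd.Series,
                        th: RRThresholds) -> pd.Series:
    """Low / Normal / High classes; band boundaries are Normal; missing
    values stay missing."""
    s = pd.Series(values, dtype=float)
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    out[s < th.lower] = "Low"
    out[s > th.upper] = "High"
    out[(s >= th.lower) & (s <= th.upper)] = "Normal"
    return out


def collapse_tables(class_counts: pd.DataFrame
                    ) -> tuple[ContingencyTable, ContingencyTable]:
    """Collapse genotype x {Low, Normal, High} counts into the two
    directional 2x2 tables.

    ``class_counts``: index = genotype levels (reference first), columns =
    Low/Normal/High.  ``high_table`` merges Low+Normal against High;
    ``low_table`` keeps Low against Normal+High.
    """
    cc = class_counts[list(CLASSES)].to_numpy(dtype=np.int64)
    genos = [str(g) for g in class_counts.index]
    high = np.vstack([cc[:, 0] + cc[:, 1], cc[:, 2]])
    low = np.vstack([cc[:, 0], cc[:, 1] + cc[:, 2]])
    stratum = "collapsed"
    return (ContingencyTable(["Low+Normal", "High"], genos, high, stratum),
            ContingencyTable(["Low", "Normal+High"], genos, low, stratum))


@dataclass
class RRResult:
    strata: dict[str, dict[str, Any]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def genotype_p(self) -> float | None:
        """Smaller of the two directional p-values of the main stratum."""
        main = self.strata.get("all")
        if main is None:
            return None
        ps = [main[k]["p_value"] for k in ("high_test", "low_test")
              if main.get(k) is not None and main[k].get("p_value") is not None]
        return min(ps) if ps else None

    def to_dict(self) -> dict[str, Any]:
        return {"framework": "RRplus", "strata": self.strata,
                "skipped": dict(self.skipped), "genotype_p": self.genotype_p}


def _direction_outcome(table: ContingencyTable) -> dict[str, Any] | None:
    """Exact 2x2 outcome for one collapsed direction, or a degenerate
    record (p absent) when a margin is empty."""
    try:
        out = fisher_exact_2x2(table)
        d = out.to_dict()
        d["table"] = table.to_dict()
        return d
    except DegenerateTableError as exc:
        return {"p_value": None, "degenerate": str(exc),
                "table": table.to_dict()}


def _rr_one_stratum(ds: PhenDataset, mask: pd.Series, q: float,
                    label: str) -> dict[str, Any] | None:
    df = ds.data[mask]
    resp = df[ds.spec.response]
    ctrl_mask = df[GENOTYPE].astype(str) == ds.reference_genotype
    controls = resp[ctrl_mask].dropna()
    if controls.size < 2:
        return None
    th = control_thresholds(controls, q=q, stratum=label)
    classes = discretize_response(resp, th)
    keep = classes.notna()
    genos = df[GENOTYPE].astype(str)[keep]
    order = [g for g in ds.genotype_levels if g in set(genos)]
    counts = pd.DataFrame(0, index=order, columns=list(CLASSES), dtype=np.int64)
    for g, c in zip(genos, classes[keep]):
        counts.loc[g, c] += 1
    entry: dict[str, Any] = {
        "thresholds": th.to_dict(),
        "class_counts": {g: {c: int(counts.loc[g, c]) for c in CLASSES}
                         for g in order},
    }
    if len(order) < 2:
        entry["degenerate"] = "only one genotype present in stratum"
        entry["high_test"] = entry["low_test"] = None
        return entry
    high_t, low_t = collapse_tables(counts)
    high_t.stratum = low_t.stratum = label
    entry["high_test"] = _direction_outcome(high_t)
    entry["low_test"] = _direction_outcome(low_t)
    degenerate = [k for k in ("high_test", "low_test")
                  if entry[k] is not None and entry[k].get("p_value") is None]
    if degenerate:
        entry["degenerate"] = "untestable direction(s): " + ", ".join(degenerate)
    return entry


def analyze_rr(ds: PhenDataset, spec: ModelSpec | None = None) -> RRResult:
    """Run RR+ for the main effect, per-sex strata, and any further
    categorical covariates named in the spec (one stratum per level with
    at least two controls)."""
    spec = spec if spec is not None else ds.spec
    if not pd.api.types.is_numeric_dtype(ds.data[spec.response]):
        raise ValidationError("RRplus requires a numeric response")
    q = spec.rr_quantile
    result = RRResult()
    all_mask = pd.Series(True, index=ds.data.index)
    entry = _rr_one_stratum(ds, all_mask, q, "all")
    if entry is None:
        result.skipped["all"] = "no controls in stratum"
    else:
        result.strata["all"] = entry

    strata: list[tuple[str, pd.Series]] = []
    if SEX in ds.data.columns:
        sexes = sorted(ds.data[SEX].dropna().astype(str).unique())
        if len(sexes) > 1:
            for s in sexes:
                strata.append((s, ds.data[SEX].astype(str) == s))
    extra = [c for c in spec.term_columns()
             if c not in (GENOTYPE, SEX, spec.response)
             and c in ds.data.columns
             and not pd.api.types.is_numeric_dtype(ds.data[c])]
    for col in extra:
        for lev in sorted(ds.data[col].dropna().astype(str).unique()):
            strata.append((f"{col}={lev}", ds.data[col].astype(str) == lev))

    for label, mask in strata:
        entry = _rr_one_stratum(ds, mask, q, label)
        if entry is None:
            result.skipped[label] = "no controls in stratum"
        else:
            result.strata[label] = entry
    return result
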
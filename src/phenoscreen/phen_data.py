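"""Data ingestion and preparation for phenotyping screens.

The first two layers of the workflow: read a long-format specimen table,
unify column terminology (``sex``/``gender`` -> ``Sex`` and the like),
apply the missing-value and redundancy policies, and bind a declarative
model specification to the cleaned data, degrading it deterministically
where the data cannot support a term (single observed sex, dropped
body-weight column, single-level random group).

Row-level missingness is deliberately *not* resolved here: analysis
engines perform complete-case filtering on exactly the variables their
model uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = ["", "NA", "NaN", "nan"]

#: roles whose unified names the rest of the pipeline relies on
RESPONSE, GENOTYPE, SEX, BODYWEIGHT, BATCH, LIFESTAGE = (
    "Response", "Genotype", "Sex", "BodyWeight", "Batch", "LifeStage",
)

LMM, FISHER, RRPLUS = "LMM", "FisherExact", "RRplus"
FRAMEWORKS = (LMM, FISHER, RRPLUS)

#: candidate labels recognised as the control / wild-type genotype when the
#: user does not name a reference level explicitly
CONTROL_LABELS = ("control", "wt", "wildtype", "wild type", "wild_type", "+/+")


class ValidationError(ValueError):
    """Raised when the data or the model specification is inconsistent."""


def _load_synonyms(extra: Mapping[str, str] | None = None) -> dict[str, str]:
    """Packaged synonym dictionary (lower-cased original -> unified name),
    optionally extended by the caller."""
    with resources.files(__package__).joinpath("synonyms.json").open() as fh:
        packaged = json.load(fh)
    table = {k.lower(): v for k, v in packaged["columns"].items()}
    if extra:
        table.update({k.lower(): v for k, v in extra.items()})
    return table


def _sex_value_map() -> dict[str, str]:
    with resources.files(__package__).joinpath("synonyms.json").open() as fh:
        packaged = json.load(fh)
    return {k.lower(): v for k, v in packaged["sex_values"].items()}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PrepReport:
    """Record of every preparation action taken on the raw table."""

    dropped_variables: list[tuple[str, str]] = field(default_factory=list)
    substituted_counts: dict[str, int] = field(default_factory=dict)
    renamed: dict[str, str] = field(default_factory=dict)
    constant_columns: list[str] = field(default_factory=list)
    degradations: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "dropped_variables": [list(t) for t in self.dropped_variables],
            "substituted_counts": dict(self.substituted_counts),
            "renamed": dict(self.renamed),
            "constant_columns": list(self.constant_columns),
            "degradations": list(self.degradations),
        }


@dataclass
class RawTable:
    """A parsed specimen table plus the cumulative preparation report."""

    data: pd.DataFrame
    source: str = "in-memory"
    prep: PrepReport = field(default_factory=PrepReport)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ModelSpec:
    """Declarative description of the analysis to run.

    ``fixed_terms`` are column names; a pairwise interaction is written
    ``"A:B"``.  ``framework`` selects the engine: ``LMM`` (continuous,
    mixed model), ``FisherExact`` (categorical) or ``RRplus`` (continuous
    discretized against the control distribution).
    """

    framework: str = LMM
    response: str = RESPONSE
    fixed_terms: list[str] = field(
        default_factory=lambda: [GENOTYPE, SEX, f"{GENOTYPE}:{SEX}", BODYWEIGHT])
    random_groups: list[str] = field(default_factory=lambda: [BATCH])
    reference_genotype: str | None = None
    rr_quantile: float = 0.95
    optimize: str = "none"
    mc_draws: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise ValidationError(f"unknown framework {self.framework!r}")
        if not (0.5 < self.rr_quantile < 1.0):
            raise ValidationError("rr_quantile must lie strictly in (0.5, 1)")
        if self.optimize not in ("none", "forward", "backward", "stepwise"):
            raise ValidationError(f"unknown optimize mode {self.optimize!r}")
        if self.mc_draws < 1:
            raise ValidationError("mc_draws must be positive")

    def term_columns(self) -> list[str]:
        """All data columns referenced by fixed terms (interactions split)."""
        cols: list[str] = []
        for t in self.fixed_terms:
            for c in t.split(":"):
                if c not in cols:
                    cols.append(c)
        return cols


def default_spec(framework: str, **overrides: Any) -> ModelSpec:
    """The standard screening model for each framework.

    Continuous responses use Genotype + Sex + Genotype:Sex + BodyWeight with
    a batch random intercept; the categorical and reference-range frameworks
    stratify on Sex rather than modelling it.
    """
    if framework == LMM:
        return ModelSpec(framework=LMM, **overrides)
    if framework == FISHER:
        base = dict(framework=FISHER, fixed_terms=[GENOTYPE, SEX],
                    random_groups=[])
        base.update(overrides)
        return ModelSpec(**base)
    if framework == RRPLUS:
        base = dict(framework=RRPLUS, fixed_terms=[GENOTYPE, SEX],
                    random_groups=[])
        base.update(overrides)
        return ModelSpec(**base)
    raise ValidationError(f"unknown framework {framework!r}")


@dataclass
class PhenDataset:
    """A validated dataset bound to a (possibly degraded) model spec."""

    data: pd.DataFrame
    spec: ModelSpec
    prep: PrepReport
    fallback_fixed_only: bool = False

    @property
    def response(self) -> pd.Series:
        return self.data[self.spec.response]

    @property
    def genotype(self) -> pd.Series:
        return self.data[GENOTYPE]

    @property
    def reference_genotype(self) -> str:
        assert self.spec.reference_genotype is not None
        return self.spec.reference_genotype

    @property
    def genotype_levels(self) -> list[str]:
        """Observed genotype levels, reference first, others in appearance order."""
        ref = self.reference_genotype
        seen = [g for g in self.data[GENOTYPE].dropna().astype(str) ]
        order: list[str] = [ref]
        for g in seen:
            if g not in order:
                order.append(g)
        return order

    @property
    def has_sex(self) -> bool:
        return SEX in self.data.columns and self.data[SEX].dropna().nunique() > 1

    @property
    def has_lifestage(self) -> bool:
        return LIFESTAGE in self.data.columns and self.data[LIFESTAGE].dropna().nunique() > 0

    def is_control(self) -> pd.Series:
        return self.data[GENOTYPE].astype(str) == self.reference_genotype


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_table(path: str | Path, delimiter: str | None = None) -> RawTable:
    """Read a delimited text file with a header row into a :class:`RawTable`.

    The delimiter is sniffed from the extension (``.tsv`` -> tab) when not
    given.  Empty strings, ``NA`` and ``NaN`` are read as missing;
    numeric-looking columns are typed numeric.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=delimiter, na_values=MISSING_TOKENS,
                         keep_default_na=False, skipinitialspace=True)
    except OSError:
        raise
    except Exception as exc:  # malformed content
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    dupes = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    # pandas mangles duplicate headers to name.1, name.2 ...; detect and refuse
    originals = set(df.columns)
    collided = sorted({d.rsplit(".", 1)[0] for d in dupes
                       if d.rsplit(".", 1)[0] in originals})
    if collided:
        raise ValidationError(f"duplicate header names: {', '.join(collided)}")
    if len(df) == 0:
        raise ValidationError("empty table: header present but no data rows")
    return RawTable(data=df, source=str(path))


def normalize_terms(raw: RawTable,
                    extra_synonyms: Mapping[str, str] | None = None) -> RawTable:
    """Unify column terminology and harmonize Sex level spellings.

    ``sex``/``gender`` become ``Sex``; ``weight``/``body_weight`` become
    ``BodyWeight``; ``batch``/``date_of_experiment``/``assay_date`` become
    ``Batch``; ``genotype``/``biological_sample_group`` become ``Genotype``.
    Unrecognized columns are left untouched.  Idempotent.
    """
    table = _load_synonyms(extra_synonyms)
    df = raw.data.copy()
    prep = replace(raw.prep,
                   renamed=dict(raw.prep.renamed),
                   dropped_variables=list(raw.prep.dropped_variables),
                   substituted_counts=dict(raw.prep.substituted_counts),
                   constant_columns=list(raw.prep.constant_columns),
                   degradations=list(raw.prep.degradations))
    rename: dict[str, str] = {}
    for col in df.columns:
        target = table.get(col.lower())
        if target is not None and col != target:
            rename[col] = target
    targets = list(rename.values())
    collisions = sorted({t for t in targets
                         if targets.count(t) > 1 or t in df.columns})
    if collisions:
        raise ValidationError(
            "columns collide onto the same unified name(s): "
            + ", ".join(collisions))
    df = df.rename(columns=rename)
    prep.renamed.update(rename)
    if SEX in df.columns:
        vmap = _sex_value_map()
        df[SEX] = df[SEX].map(
            lambda v: vmap.get(str(v).strip().lower(), v) if pd.notna(v) else v)
    return RawTable(data=df, source=raw.source, prep=prep)


def handle_missing(raw: RawTable, threshold: float = 0.5,
                   substitutions: Mapping[str, Any] | None = None) -> RawTable:
    """Drop columns whose missing fraction strictly exceeds ``threshold``.

    A column with a supplied substitution value is retained with its
    missing entries filled instead; the number of fills is recorded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("missing threshold must lie in (0, 1)")
    substitutions = dict(substitutions or {})
    df = raw.data.copy()
    prep = replace(raw.prep,
                   renamed=dict(raw.prep.renamed),
                   dropped_variables=list(raw.prep.dropped_variables),
                   substituted_counts=dict(raw.prep.substituted_counts),
                   constant_columns=list(raw.prep.constant_columns),
                   degradations=list(raw.prep.degradations))
    n = len(df)
    for col in list(df.columns):
        n_missing = int(df[col].isna().sum())
        if col in substitutions and n_missing > 0:
            value = substitutions[col]
            if pd.api.types.is_numeric_dtype(df[col]) and not isinstance(
                    value, (int, float, np.integer, np.floating)):
                raise ValidationError(
                    f"substitution for numeric column {col!r} must be numeric, "
                    f"got {value!r}")
            df[col] = df[col].fillna(value)
            prep.substituted_counts[col] = (
                prep.substituted_counts.get(col, 0) + n_missing)
        elif n_missing / n > threshold:
            df = df.drop(columns=[col])
            prep.dropped_variables.append((col, "missing>50%"))
    return RawTable(data=df, source=raw.source, prep=prep)


def drop_redundant(raw: RawTable, tol: float = 1e-12) -> RawTable:
    """Remove duplicated columns and numeric pairs with |Pearson r| = 1.

    The column appearing first in the table wins.  Correlation is computed
    on complete cases of each pair; ``tol`` absorbs floating-point noise in
    exactly collinear pairs.  Constant columns are flagged but retained.
    """
    df = raw.data.copy()
    prep = replace(raw.prep,
                   renamed=dict(raw.prep.renamed),
                   dropped_variables=list(raw.prep.dropped_variables),
                   substituted_counts=dict(raw.prep.substituted_counts),
                   constant_columns=list(raw.prep.constant_columns),
                   degradations=list(raw.prep.degradations))
    cols = list(df.columns)
    to_drop: list[str] = []
    for i, a in enumerate(cols):
        if a in to_drop:
            continue
        for b in cols[i + 1:]:
            if b in to_drop:
                continue
            sa, sb = df[a], df[b]
            if sa.equals(sb):
                to_drop.append(b)
                continue
            if (pd.api.types.is_numeric_dtype(sa)
                    and pd.api.types.is_numeric_dtype(sb)):
                pair = df[[a, b]].dropna()
                if len(pair) < 2:
                    continue
                x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if abs(abs(r) - 1.0) <= tol:
                    to_drop.append(b)
    for col in to_drop:
        df = df.drop(columns=[col])
        prep.dropped_variables.append((col, "redundant"))
    for col in df.columns:
        if df[col].dropna().nunique() == 1 and col not in prep.constant_columns:
            prep.constant_columns.append(col)
    return RawTable(data=df, source=raw.source, prep=prep)


def _resolve_reference(levels: Sequence[str], requested: str | None) -> str:
    if requested is not None:
        if requested not in levels:
            raise ValidationError(
                f"reference genotype {requested!r} not observed in data")
        return requested
    for lab in levels:
        if str(lab).strip().lower() in CONTROL_LABELS:
            return lab
    raise ValidationError(
        "no reference genotype given and no recognizable control label among "
        f"{list(levels)}")


def validate_spec(raw: RawTable, spec: ModelSpec) -> PhenDataset:
    """Check model/data concordance and bind the spec to the data.

    Hard errors: missing Genotype column, fewer than two genotype levels,
    unobserved reference level, response type incompatible with the chosen
    framework.  Recoverable problems degrade the spec deterministically and
    are recorded: Sex terms dropped when one sex is observed, BodyWeight
    dropped when its column was removed upstream, single-level random
    groups dropped (setting the fixed-only fallback flag).
    """
    df = raw.data
    prep = replace(raw.prep,
                   renamed=dict(raw.prep.renamed),
                   dropped_variables=list(raw.prep.dropped_variables),
                   substituted_counts=dict(raw.prep.substituted_counts),
                   constant_columns=list(raw.prep.constant_columns),
                   degradations=list(raw.prep.degradations))

    if GENOTYPE not in df.columns:
        raise ValidationError("essential term absent: Genotype")
    if spec.response not in df.columns:
        raise ValidationError(f"response column {spec.response!r} absent")

    geno = df[GENOTYPE].dropna().astype(str)
    levels = list(dict.fromkeys(geno))
    if len(levels) < 2:
        raise ValidationError(
            f"Genotype must have at least 2 observed levels, found {levels}")
    reference = _resolve_reference(levels, spec.reference_genotype)

    resp = df[spec.response]
    numeric = pd.api.types.is_numeric_dtype(resp)
    if spec.framework in (LMM, RRPLUS) and not numeric:
        raise ValidationError(
            f"type mismatch: framework {spec.framework} requires a numeric "
            "response")
    if spec.framework == FISHER and numeric:
        raise ValidationError(
            "type mismatch: framework FisherExact requires a categorical "
            "response")

    fixed = list(spec.fixed_terms)
    single_sex = SEX not in df.columns or df[SEX].dropna().nunique() < 2
    if single_sex:
        for t in list(fixed):
            if SEX in t.split(":"):
                fixed.remove(t)
                prep.degradations.append(
                    f"dropped term {t!r}: fewer than two sexes observed")
    for t in list(fixed):
        missing_cols = [c for c in t.split(":") if c not in df.columns]
        if missing_cols:
            dropped_upstream = {name for name, _ in prep.dropped_variables}
            if all(c in dropped_upstream for c in missing_cols):
                fixed.remove(t)
                prep.degradations.append(
                    f"dropped term {t!r}: column(s) "
                    f"{missing_cols} removed during preparation")
            else:
                raise ValidationError(
                    f"model term {t!r} references absent column(s) "
                    f"{missing_cols}")
    # interactions must keep both main effects (hierarchy)
    for t in list(fixed):
        parts = t.split(":")
        if len(parts) == 2 and not all(p in fixed for p in parts):
            fixed.remove(t)
            prep.degradations.append(
                f"dropped interaction {t!r}: a main effect is unavailable")

    random_groups = []
    fallback = False
    for g in spec.random_groups:
        if g not in df.columns:
            dropped_upstream = {name for name, _ in prep.dropped_variables}
            if g in dropped_upstream:
                prep.degradations.append(
                    f"dropped random group {g!r}: column removed during "
                    "preparation")
                fallback = True
                continue
            raise ValidationError(f"random group {g!r} references absent column")
        if df[g].dropna().nunique() < 2:
            prep.degradations.append(
                f"dropped random group {g!r}: single observed level")
            fallback = True
            continue
        random_groups.append(g)
    if spec.framework != LMM:
        random_groups = []
        fallback = False

    bound = replace(spec, fixed_terms=fixed, random_groups=random_groups,
                    reference_genotype=reference)
    return PhenDataset(data=df, spec=bound, prep=prep,
                       fallback_fixed_only=fallback and spec.framework == LMM)


def summarize_dataset(ds: PhenDataset) -> dict[str, Any]:
    """Per-group counts, response summaries and missingness per variable."""
    df = ds.data
    group_cols = [GENOTYPE] + ([SEX] if SEX in df.columns else [])
    counts = (df.groupby(group_cols, dropna=False, observed=True)
              .size().reset_index(name="n"))
    group_counts = [
        {**{c: (None if pd.isna(row[c]) else str(row[c])) for c in group_cols},
         "n": int(row["n"])}
        for _, row in counts.iterrows()
    ]
    resp = ds.response
    if pd.api.types.is_numeric_dtype(resp):
        clean = resp.dropna().astype(float)
        response_summary = {
            "type": "continuous",
            "n": int(clean.size),
            "mean": float(clean.mean()) if clean.size else None,
            "sd": float(clean.std(ddof=1)) if clean.size > 1 else None,
            "median": float(clean.median()) if clean.size else None,
            "q1": float(clean.quantile(0.25)) if clean.size else None,
            "q3": float(clean.quantile(0.75)) if clean.size else None,
        }
    else:
        freq = resp.dropna().astype(str).value_counts()
        response_summary = {
            "type": "categorical",
            "n": int(resp.notna().sum()),
            "levels": {str(k): int(v) for k, v in freq.items()},
        }
    missing = {c: int(df[c].isna().sum()) for c in df.columns}
    return {
        "group_counts": group_counts,
        "response": response_summary,
        "missing_per_variable": missing,
        "n_rows": int(len(df)),
    }


def prepare(raw: RawTable, spec: ModelSpec, *,
            missing_threshold: float = 0.5,
            substitutions: Mapping[str, Any] | None = None) -> PhenDataset:
    """Run the full preparation chain: normalize -> missing -> redundancy ->
    validate, returning the bound dataset."""
    step = normalize_terms(raw)
    step = handle_missing(step, threshold=missing_threshold,
                          substitutions=substitutions)
    step = drop_redundant(step)
    return validate_spec(step, spec)
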
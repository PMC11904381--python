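"""Synthetic CBC cohort generation.

The six study cohorts (five Italian hospitals, emergency-department and
intensive-care settings) were never deposited; this module generates labeled
synthetic stand-ins whose marginal feature distributions, sepsis prevalence,
sex ratio and missingness structure match the published per-cohort summary
statistics, so that every downstream stage (model fitting, cautious
classification, imputation, external validation) is testable end to end.

Feature values are drawn class-conditionally from one-sided truncated normal
distributions: non-sepsis rows at the cohort reference (mean, SD), sepsis rows
with the mean displaced by a configurable standardized effect size. The
neutrophils-to-lymphocytes ratio (NLR) is always recomputed from the drawn
neutrophil and lymphocyte counts rather than drawn independently. Labeling
criterion shift (sepsis-2 vs sepsis-3) is emulated by flipping the labels of
the rows nearest the class boundary in MDW. Features are drawn on independent
seeded sub-streams so adding or removing a feature never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURE_NAMES",
    "LABEL_COLUMN",
    "FeatureSpec",
    "CohortSpec",
    "FeatureTable",
    "CohortSpecError",
    "TableParseError",
    "builtin_cohort_specs",
    "cohort_spec_from_dict",
    "generate_cohort",
    "read_table",
    "write_table",
]

#: Canonical column order of the 19 features (the CSV interchange order).
#: ``sex`` is coded 1 = male, 0 = female; all other features are continuous
#: laboratory values in their conventional units.
FEATURE_NAMES: tuple[str, ...] = (
    "age", "sex", "wbc", "neutrophils", "monocytes", "mdw", "crp",
    "lymphocytes", "eosinophils", "basophils", "rbc", "hgb", "hct",
    "mcv", "mch", "mchc", "rdw", "plt", "nlr",
)

LABEL_COLUMN = "sepsis"

# Default standardized mean shifts added to sepsis-class rows, chosen so MDW
# is the dominant predictor, consistent with MDW being the single most
# predictive feature in this panel, followed by CRP and the leucocyte counts.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "mdw": 2.0,
    "crp": 1.5,
    "neutrophils": 1.0,
    "lymphocytes": -0.5,
}

# Sub-stream indices for seeded reproducibility (one master seed per cohort,
# deterministic per-purpose children).
_STREAM_LABELS = 100
_STREAM_MISSING_BASE = 200


class CohortSpecError(ValueError):
    """A cohort specification violates an invariant; names the field."""


class TableParseError(ValueError):
    """A CSV table could not be parsed; carries row/column coordinates."""


@dataclass(frozen=True)
class FeatureSpec:
    """Marginal distribution parameters for one feature.

    ``kind='continuous'`` features are drawn from a normal truncated below at
    ``lower_bound``; ``kind='binary'`` features (sex) are Bernoulli with
    success probability ``mean``.
    """

    name: str
    mean: float
    sd: float
    lower_bound: float = 0.0
    kind: str = "continuous"

    def validate(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise CohortSpecError(f"unknown feature name: {self.name!r}")
        if self.sd < 0:
            raise CohortSpecError(f"features[{self.name}].sd must be >= 0, got {self.sd}")
        if self.kind not in ("continuous", "binary"):
            raise CohortSpecError(f"features[{self.name}].kind invalid: {self.kind!r}")
        if self.kind == "continuous" and self.lower_bound > self.mean:
            raise CohortSpecError(
                f"features[{self.name}].lower_bound {self.lower_bound} exceeds mean {self.mean}"
            )
        if self.kind == "binary" and not 0.0 <= self.mean <= 1.0:
            raise CohortSpecError(f"features[{self.name}].mean must be in [0,1] for binary kind")


@dataclass(frozen=True)
class CohortSpec:
    """Full parametric description of one synthetic cohort."""

    cohort_id: str
    n: int
    prevalence: float
    features: dict[str, FeatureSpec]
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    missingness: dict[str, float] = field(default_factory=dict)
    label_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise CohortSpecError(f"n must be >= 10, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise CohortSpecError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0.0 <= self.label_noise < 1.0:
            raise CohortSpecError(f"label_noise must be in [0,1), got {self.label_noise}")
        missing_feats = [f for f in FEATURE_NAMES if f not in self.features]
        if missing_feats:
            raise CohortSpecError(f"features missing specs for: {missing_feats}")
        for fs in self.features.values():
            fs.validate()
        for name, frac in self.missingness.items():
            if name not in FEATURE_NAMES:
                raise CohortSpecError(f"missingness key {name!r} is not a known feature")
            if not 0.0 <= frac <= 1.0:
                raise CohortSpecError(f"missingness[{name}] must be in [0,1], got {frac}")
        for name in self.effect_sizes:
            if name not in FEATURE_NAMES:
                raise CohortSpecError(f"effect_sizes key {name!r} is not a known feature")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FeatureTable:
    """Labeled patient-by-feature matrix with an explicit missingness mask.

    ``mask[i, j]`` is True iff cell (i, j) is missing; missing cells hold NaN
    and NaN never appears outside masked cells. Column order is fixed to
    :data:`FEATURE_NAMES`.
    """

    ids: np.ndarray
    columns: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.ids = np.asarray(self.ids)
        self.columns = tuple(self.columns)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in table") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    def column_mask(self, name: str) -> np.ndarray:
        return self.mask[:, self.column_index(name)]

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            ids=self.ids[rows],
            columns=self.columns,
            values=self.values[rows],
            mask=self.mask[rows],
            labels=self.labels[rows],
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            ids=self.ids.copy(),
            columns=self.columns,
            values=self.values.copy(),
            mask=self.mask.copy(),
            labels=self.labels.copy(),
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.columns == other.columns
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def validate(self) -> None:
        n, p = self.values.shape
        if self.mask.shape != (n, p) or self.labels.shape != (n,):
            raise ValueError("values/mask/labels shapes disagree")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        nan_cells = np.isnan(self.values)
        if (nan_cells & ~self.mask).any():
            raise ValueError("NaN outside masked cells")
        # NLR functional dependence where its components are observed
        neut, lymph = self.column("neutrophils"), self.column("lymphocytes")
        obs = ~(self.column_mask("neutrophils") | self.column_mask("lymphocytes")
                | self.column_mask("nlr"))
        nlr = self.column("nlr")
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = neut[obs] / lymph[obs]
        if obs.any() and not np.allclose(nlr[obs], expected, rtol=1e-9, atol=0):
            raise ValueError("NLR column inconsistent with neutrophils/lymphocytes")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df[LABEL_COLUMN] = self.labels.astype(int)
        return df


# --------------------------------------------------------------------------
# Built-in cohort parameterizations (published per-cohort summary statistics)
# --------------------------------------------------------------------------

# (mean, sd) per continuous feature, per cohort, in FEATURE_NAMES order minus
# sex; sex is (male fraction). OGSA-ICU's MDW was never measured (its analyzer
# does not report MDW): the latent MDW distribution below is the PA-ED
# reference, a neutral stand-in that is fully masked and never observable.
_T1 = {
    "PA-ED": dict(
        n=1809, prevalence=0.0459, male=0.4859,
        age=(55.1, 20.0), wbc=(10.2, 4.1), neutrophils=(7.2, 3.9),
        monocytes=(0.8, 0.3), mdw=(20.1, 3.2), crp=(22.6, 49.3),
        lymphocytes=(2.1, 1.1), eosinophils=(0.1, 0.2), basophils=(0.1, 0.1),
        rbc=(4.6, 0.7), hgb=(13.4, 2.1), hct=(39.3, 5.9), mcv=(86.5, 7.9),
        mch=(29.5, 3.2), mchc=(34.0, 1.2), rdw=(14.6, 2.1), plt=(254.4, 90.4),
        nlr=(5.0, 5.7),
    ),
    "AR-ED": dict(
        n=308, prevalence=0.247, male=0.549,
        age=(69.0, 21.4), wbc=(11.3, 6.4), neutrophils=(8.7, 5.4),
        monocytes=(0.8, 0.4), mdw=(25.6, 6.4), crp=(83.0, 93.0),
        lymphocytes=(1.6, 3.6), eosinophils=(0.1, 0.2), basophils=(0.0, 0.1),
        rbc=(4.2, 0.8), hgb=(12.3, 2.3), hct=(37.6, 6.5), mcv=(91.0, 6.7),
        mch=(29.6, 2.4), mchc=(32.5, 1.1), rdw=(15.8, 2.4), plt=(229.6, 105.2),
        nlr=(10.3, 11.3),
    ),
    "PA-ICU": dict(
        n=75, prevalence=0.29, male=0.61,
        age=(66.5, 13.0), wbc=(13.9, 6.6), neutrophils=(12.7, 6.7),
        monocytes=(0.8, 0.4), mdw=(24.6, 7.5), crp=(81.4, 96.5),
        lymphocytes=(1.0, 0.5), eosinophils=(0.1, 0.5), basophils=(0.0, 0.0),
        rbc=(3.9, 0.8), hgb=(10.9, 2.3), hct=(32.6, 7.0), mcv=(85.3, 9.5),
        mch=(29.3, 7.7), mchc=(33.1, 1.5), rdw=(48.0, 7.6), plt=(243.3, 120.8),
        nlr=(18.0, 19.1),
    ),
    "PD-ICU": dict(
        n=2114, prevalence=0.3354, male=0.7625,
        age=(66.3, 14.9), wbc=(11.5, 5.4), neutrophils=(9.4, 5.0),
        monocytes=(0.9, 0.5), mdw=(24.1, 5.0), crp=(93.9, 81.0),
        lymphocytes=(1.0, 0.6), eosinophils=(0.2, 0.4), basophils=(0.0, 0.1),
        rbc=(3.5, 0.6), hgb=(10.4, 1.5), hct=(31.7, 4.8), mcv=(90.1, 6.1),
        mch=(29.5, 2.2), mchc=(32.7, 0.9), rdw=(15.7, 2.9), plt=(236.7, 145.3),
        nlr=(14.4, 17.2),
    ),
    "UD-ED": dict(
        n=938, prevalence=0.067, male=0.47,
        age=(66.5, 19.2), wbc=(8.9, 4.6), neutrophils=(6.4, 3.8),
        monocytes=(0.7, 0.4), mdw=(21.2, 4.2), crp=(25.3, 52.9),
        lymphocytes=(1.7, 2.3), eosinophils=(0.1, 0.1), basophils=(0.0, 0.0),
        rbc=(4.4, 0.7), hgb=(13.1, 2.1), hct=(38.8, 5.8), mcv=(88.9, 6.4),
        mch=(30.1, 2.6), mchc=(33.8, 1.0), rdw=(14.7, 2.1), plt=(241.7, 88.5),
        nlr=(5.8, 7.1),
    ),
    "OGSA-ICU": dict(
        n=100, prevalence=0.06, male=0.50,
        age=(64.3, 18.1), wbc=(13.4, 6.2), neutrophils=(12.3, 9.4),
        monocytes=(0.8, 0.5), mdw=(20.1, 3.2), crp=(56.6, 80.7),
        lymphocytes=(1.2, 1.9), eosinophils=(0.1, 0.1), basophils=(0.1, 0.1),
        rbc=(3.9, 0.6), hgb=(11.5, 1.8), hct=(34.3, 5.1), mcv=(89.1, 5.3),
        mch=(29.9, 2.3), mchc=(66.1, 327.5), rdw=(14.5, 2.2), plt=(196.3, 89.5),
        nlr=(16.7, 15.8),
    ),
}

# Physical floors. Lymphocytes are floored at 0.1 (not 0) so the derived NLR
# stays finite; age at 18 (adult inclusion criterion).
_LOWER_BOUNDS = {"age": 18.0, "lymphocytes": 0.1}

# External cohorts diagnosed with sepsis-3 (vs sepsis-2 in the training
# cohort) get a small borderline-relabeling noise fraction by default.
_SEPSIS3_COHORTS = ("AR-ED", "PA-ICU", "PD-ICU")
_DEFAULT_LABEL_NOISE = 0.02


def builtin_cohort_specs(seed: int = 0) -> dict[str, CohortSpec]:
    """The six study-cohort parameterizations, keyed by cohort id.

    Each spec reproduces the published per-cohort feature means/SDs, sex
    ratio, sepsis prevalence and sample size; OGSA-ICU has MDW 100% missing.
    Per-cohort seeds are derived deterministically from ``seed``.
    """
    specs: dict[str, CohortSpec] = {}
    for i, (cid, row) in enumerate(_T1.items()):
        features = {"sex": FeatureSpec("sex", mean=row["male"], sd=0.0, kind="binary")}
        for name in FEATURE_NAMES:
            if name == "sex":
                continue
            mean, sd = row[name]
            features[name] = FeatureSpec(
                name, mean=mean, sd=sd,
                lower_bound=min(_LOWER_BOUNDS.get(name, 0.0), mean),
            )
        specs[cid] = CohortSpec(
            cohort_id=cid,
            n=row["n"],
            prevalence=row["prevalence"],
            features=features,
            missingness={"mdw": 1.0} if cid == "OGSA-ICU" else {},
            label_noise=_DEFAULT_LABEL_NOISE if cid in _SEPSIS3_COHORTS else 0.0,
            seed=seed * 1009 + i,
        )
    return specs


def cohort_spec_from_dict(payload: dict) -> CohortSpec:
    """Build a validated CohortSpec from a plain mapping (e.g. parsed YAML).

    Expected keys: cohort_id, n, prevalence, features (name -> {mean, sd,
    lower_bound, kind}), and optionally effect_sizes, missingness,
    label_noise, seed. Features omitted from the mapping are an error, so a
    spec file is always complete and self-describing.
    """
    try:
        features = {
            name: FeatureSpec(
                name=name,
                mean=float(fs["mean"]),
                sd=float(fs.get("sd", 0.0)),
                lower_bound=float(fs.get("lower_bound", 0.0)),
                kind=str(fs.get("kind", "continuous")),
            )
            for name, fs in payload["features"].items()
        }
        spec = CohortSpec(
            cohort_id=str(payload["cohort_id"]),
            n=int(payload["n"]),
            prevalence=float(payload["prevalence"]),
            features=features,
            effect_sizes={k: float(v) for k, v in payload.get("effect_sizes", {}).items()},
            missingness={k: float(v) for k, v in payload.get("missingness", {}).items()},
            label_noise=float(payload.get("label_noise", 0.0)),
            seed=int(payload.get("seed", 0)),
        )
    except KeyError as exc:
        raise CohortSpecError(f"spec mapping lacks required key: {exc}") from exc
    spec.validate()
    return spec


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def _stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, index]))


def _draw_truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw one synthetic cohort from its parametric description.

    Fully reproducible from ``spec.seed``: per-feature draws, labels, the
    borderline label flips, and the missingness mask each use their own
    deterministic sub-stream of the master seed.
    """
    spec.validate()
    n = spec.n
    labels = (_stream(spec.seed, _STREAM_LABELS).random(n) < spec.prevalence).astype(np.int8)
    pos = labels == 1

    values = np.empty((n, len(FEATURE_NAMES)), dtype=float)
    for j, name in enumerate(FEATURE_NAMES):
        fs = spec.features[name]
        rng = _stream(spec.seed, j)
        if name == "nlr":
            continue  # recomputed below, never drawn
        if fs.kind == "binary":
            values[:, j] = (rng.random(n) < fs.mean).astype(float)
            continue
        es = spec.effect_sizes.get(name, 0.0)
        col = np.empty(n)
        col[~pos] = _draw_truncated_normal(
            rng, fs.mean, fs.sd, fs.lower_bound, int((~pos).sum()))
        col[pos] = _draw_truncated_normal(
            rng, fs.mean + es * fs.sd, fs.sd, fs.lower_bound, int(pos.sum()))
        values[:, j] = col

    j_nlr = FEATURE_NAMES.index("nlr")
    values[:, j_nlr] = (values[:, FEATURE_NAMES.index("neutrophils")]
                        / values[:, FEATURE_NAMES.index("lymphocytes")])

    # Label-criterion shift: flip the labels of the rows nearest the class
    # boundary in MDW (borderline cases), not random rows.
    k = int(round(spec.label_noise * n))
    if k > 0:
        mdw = values[:, FEATURE_NAMES.index("mdw")]
        fs = spec.features["mdw"]
        boundary = fs.mean + 0.5 * spec.effect_sizes.get("mdw", 0.0) * fs.sd
        nearest = np.argsort(np.abs(mdw - boundary), kind="stable")[:k]
        labels[nearest] = 1 - labels[nearest]

    mask = np.zeros_like(values, dtype=bool)
    for j, name in enumerate(FEATURE_NAMES):
        frac = spec.missingness.get(name, 0.0)
        if frac <= 0:
            continue
        rng = _stream(spec.seed, _STREAM_MISSING_BASE + j)
        col_mask = rng.random(n) < frac if frac < 1.0 else np.ones(n, dtype=bool)
        mask[:, j] = col_mask
        values[col_mask, j] = np.nan

    table = FeatureTable(
        ids=np.arange(n), columns=FEATURE_NAMES, values=values, mask=mask, labels=labels,
    )
    table.validate()
    return table


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------

_CSV_COLUMNS = FEATURE_NAMES + (LABEL_COLUMN,)


def write_table(table: FeatureTable, path) -> None:
    """Serialize to CSV (UTF-8, header, '.' decimal); missing cells empty.

    Floats are written with 17 significant digits so a write/read round trip
    is bit-exact for finite values.
    """
    df = pd.DataFrame(table.values, columns=list(table.columns))
    df[LABEL_COLUMN] = table.labels.astype(int)
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_table(path) -> FeatureTable:
    """Parse a cohort CSV into a :class:`FeatureTable`.

    Raises :class:`TableParseError` with row/column coordinates on unknown or
    absent columns and on non-numeric cells.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    unknown = [c for c in cols if c not in _CSV_COLUMNS]
    if unknown:
        raise TableParseError(f"unrecognized column(s): {unknown}")
    absent = [c for c in _CSV_COLUMNS if c not in cols]
    if absent:
        raise TableParseError(f"missing required column(s): {absent}")

    n = len(df)
    values = np.empty((n, len(FEATURE_NAMES)), dtype=float)
    mask = np.zeros((n, len(FEATURE_NAMES)), dtype=bool)
    for j, name in enumerate(FEATURE_NAMES):
        raw = df[name].to_numpy()
        empty = raw == ""
        mask[:, j] = empty
        col = np.full(n, np.nan)
        if (~empty).any():
            try:
                col[~empty] = np.asarray(raw[~empty], dtype=float)
            except ValueError:
                for i in np.nonzero(~empty)[0]:
                    try:
                        float(raw[i])
                    except ValueError:
                        raise TableParseError(
                            f"non-numeric cell at row {i}, column {name!r}: {raw[i]!r}"
                        ) from None
                raise
        values[:, j] = col

    raw_labels = df[LABEL_COLUMN].to_numpy()
    try:
        labels = np.asarray(raw_labels, dtype=float)
    except ValueError:
        bad = [i for i, v in enumerate(raw_labels) if not v.replace(".", "", 1).isdigit()]
        raise TableParseError(
            f"non-numeric label at row {bad[0]}, column {LABEL_COLUMN!r}"
        ) from None
    if not np.isin(labels, (0.0, 1.0)).all():
        bad = int(np.nonzero(~np.isin(labels, (0.0, 1.0)))[0][0])
        raise TableParseError(f"label not in {{0,1}} at row {bad}, column {LABEL_COLUMN!r}")

    table = FeatureTable(
        ids=np.arange(n), columns=FEATURE_NAMES, values=values, mask=mask,
        labels=labels.astype(np.int8),
    )
    table.validate()
    return table
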
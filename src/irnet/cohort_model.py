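"""Clinical cohort derivation for insulin-resistance marker analysis.

Implements the cohort layer of the analysis: the variable codebook, the
three IR surrogate indices (HOMA-IR, TyG index, TG/HDL ratio), the
Friedewald LDL estimate, categorical recodes of labs / blood pressure /
behaviours, composite outcome definitions (diabetes, dyslipidemia,
hypertension, obesity by BMI / WC / WHtR), the exclusion cascade and
quartile binning of the indices.

All cut-offs follow Korean clinical guideline definitions: lower bounds are
inclusive of the named threshold (FBG 126 mg/dL is already "Danger";
SBP 120 mmHg is already "Caution").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "Codebook",
    "CohortTable",
    "QuartileGrouping",
    "DomainError",
    "ValidationError",
    "DegenerateQuartileError",
    "EmptyCohortError",
    "CLINICAL_BINS",
    "compute_indices",
    "friedewald_ldl",
    "categorize_clinical",
    "define_outcomes",
    "apply_exclusions",
    "quartile_bin",
    "derive_cohort",
    "default_codebook",
    "write_exclusion_log",
]


class DomainError(ValueError):
    """An input value violates the domain of a clinical formula."""


class ValidationError(ValueError):
    """Records fall outside the configured physiological guard range."""


class DegenerateQuartileError(ValueError):
    """Fewer than four distinct values: quartile cuts collapse."""


class EmptyCohortError(ValueError):
    """All records were removed by the exclusion cascade."""


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

ROLES = ("continuous", "categorical", "outcome", "design")


@dataclass
class VariableSpec:
    name: str
    role: str
    levels: tuple = ()
    units: str = ""
    derivation: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        self.levels = tuple(self.levels)
        if self.role in ("categorical", "outcome"):
            if len(self.levels) < 2:
                raise ValueError(f"categorical variable {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")


@dataclass
class Codebook:
    """Variable registry: the single source of truth for roles and levels."""

    entries: list

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in codebook")
        design = sorted(e.name for e in self.entries if e.role == "design")
        if design and design != ["psu", "stratum", "weight"]:
            raise ValueError("design role must cover exactly weight, stratum, psu")

    def __getitem__(self, name):
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def names(self, role=None):
        return [e.name for e in self.entries if role is None or e.role == role]

    def levels(self):
        return {e.name: list(e.levels) for e in self.entries
                if e.role in ("categorical", "outcome")}

    def to_yaml(self, path):
        payload = [
            {"name": e.name, "role": e.role, "levels": list(e.levels),
             "units": e.units, "derivation": e.derivation}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls([VariableSpec(**d) for d in payload])


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Participant records plus survey-design columns (weight, stratum, psu)."""

    df: pd.DataFrame
    codebook: Codebook | None = None

    def validate(self):
        df = self.df
        if df.index.has_duplicates:
            raise ValidationError("duplicate participant ids")
        if "weight" in df.columns and (df["weight"] <= 0).any():
            raise ValidationError("survey weights must be positive")
        if {"stratum", "psu"} <= set(df.columns):
            nest = df.groupby("psu", observed=True)["stratum"].nunique()
            if (nest > 1).any():
                bad = nest[nest > 1].index.tolist()
                raise ValidationError(f"PSUs in multiple strata: {bad}")
        if self.codebook is not None:
            for name, levels in self.codebook.levels().items():
                if name in df.columns:
                    observed = set(df[name].dropna().unique())
                    if not observed <= set(levels):
                        raise ValidationError(
                            f"{name!r} has values outside declared levels: "
                            f"{sorted(observed - set(levels))}")
        return self

    def to_csv(self, path):
        self.df.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, codebook=None):
        return cls(pd.read_csv(path, index_col="id"), codebook)


# ---------------------------------------------------------------------------
# IR indices
# ---------------------------------------------------------------------------

def _aspositive(x, name):
    arr = np.asarray(x, dtype=float)
    bad = ~np.isnan(arr) & (arr <= 0)
    if bad.any():
        raise DomainError(f"{name} must be > 0 (got {arr[bad][:3].tolist()} ...)")
    return arr


def compute_indices(insulin, fbg, tg, hdl) -> pd.DataFrame:
    """HOMA-IR, TyG index and TG/HDL ratio per participant.

    HOMA-IR = insulin [uIU/mL] * FBG [mg/dL] / 405 (unitless);
    TyG = ln(TG [mg/dL] * FBG [mg/dL] / 2);
    TG/HDL = TG [mg/dL] / HDL [mg/dL].

    ``insulin`` may contain missing values (HOMA-IR is then missing, never
    zero); FBG, TG and HDL must be strictly positive.
    """
    fbg = _aspositive(fbg, "fbg")
    tg = _aspositive(tg, "tg")
    hdl = _aspositive(hdl, "hdl")
    for name, arr in (("fbg", fbg), ("tg", tg), ("hdl", hdl)):
        if np.isnan(arr).any():
            raise DomainError(f"{name} contains missing values")
    insulin = _aspositive(insulin, "insulin")
    homa = insulin * fbg / 405.0
    tyg = np.log(tg * fbg / 2.0)
    ratio = tg / hdl
    return pd.DataFrame({"homa_ir": homa, "tyg": tyg, "tg_hdl": ratio})


def friedewald_ldl(tchol, hdl, tg):
    """LDL = TCHOL - HDL - TG/5 (mg/dL), for records without measured LDL.

    Negative estimates (possible at extreme TG) are returned as-is; callers
    flag them rather than rejecting the record.
    """
    tchol = np.asarray(tchol, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    bad = ~np.isnan(tchol) & ~np.isnan(hdl) & ((hdl < 0) | (tchol < hdl))
    if bad.any():
        raise DomainError("friedewald_ldl requires tchol >= hdl >= 0")
    return tchol - hdl - tg / 5.0


# ---------------------------------------------------------------------------
# Clinical categorization
# ---------------------------------------------------------------------------

# column -> (thresholds, level labels); n thresholds give n+1 ordered bands,
# each lower bound inclusive of its threshold.
CLINICAL_BINS = {
    "sbp": ((120.0, 140.0), ("Normal", "Caution", "Danger")),
    "dbp": ((80.0, 90.0), ("Normal", "Caution", "Danger")),
    "fbg": ((100.0, 126.0), ("Normal", "Caution", "Danger")),
    "hba1c": ((5.7, 6.4), ("Normal", "Caution", "Danger")),
    "tg": ((150.0, 200.0), ("Normal", "Caution", "Danger")),
    "tchol": ((200.0, 240.0), ("Normal", "Caution", "Danger")),
    "ldl": ((130.0, 190.0), ("Normal", "Caution", "Danger")),
    "hdl": ((40.0,), ("Danger", "Normal")),  # low HDL is the risk state
}

BEHAVIOR_LEVELS = {
    "sleep": ("<6h", ">=6h"),
    "drinking": ("<1/mo", ">=1/mo"),
    "smoking": ("no", "yes"),
}

YESNO = ("no", "yes")


def _band(values, thresholds, labels):
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(thresholds), values, side="right")
    out = pd.Categorical.from_codes(
        np.where(np.isnan(values), -1, idx).astype(int), categories=list(labels))
    return out


def categorize_clinical(df: pd.DataFrame, guard_factor: float = 10.0) -> pd.DataFrame:
    """Map continuous clinical columns to their guideline bands.

    Adds one ``<var>_cat`` column per recognized lab / blood-pressure
    column, plus binary behaviour recodes (sleep, drinking, smoking).
    Values outside the physiological guard range ``[0, guard_factor * top
    threshold]`` raise :class:`ValidationError` listing the offending
    record ids.  The operation is idempotent: re-running it on a frame that
    already carries the categorical columns reproduces them.
    """
    out = df.copy()
    for col, (thresholds, labels) in CLINICAL_BINS.items():
        if col not in out.columns:
            continue
        values = pd.to_numeric(out[col], errors="raise")
        hi = guard_factor * max(thresholds)
        bad = values.notna() & ((values < 0) | (values > hi))
        if bad.any():
            raise ValidationError(
                f"{col} outside guard range [0, {hi}]: record ids "
                f"{out.index[bad].tolist()[:10]}")
        out[f"{col}_cat"] = _band(values, thresholds, labels)
    if "sleep_hours" in out.columns:
        out["sleep"] = pd.Categorical(
            np.where(out["sleep_hours"] < 6, "<6h", ">=6h"),
            categories=list(BEHAVIOR_LEVELS["sleep"]))
    if "drink_freq" in out.columns:  # drinking occasions per month
        out["drinking"] = pd.Categorical(
            np.where(out["drink_freq"] < 1, "<1/mo", ">=1/mo"),
            categories=list(BEHAVIOR_LEVELS["drinking"]))
    if {"smoked_ge5packs", "current_smoker"} & set(out.columns):
        ever = out.get("smoked_ge5packs", pd.Series("no", index=out.index)) == "yes"
        now = out.get("current_smoker", pd.Series("no", index=out.index)) == "yes"
        out["smoking"] = pd.Categorical(
            np.where(ever | now, "yes", "no"), categories=list(BEHAVIOR_LEVELS["smoking"]))
    return out


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def _flag(df, col):
    if col in df.columns:
        return df[col] == "yes", df[col].notna()
    return pd.Series(False, index=df.index), pd.Series(False, index=df.index)


def _meas(df, col, op):
    if col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        return op(vals).fillna(False), vals.notna()
    return pd.Series(False, index=df.index), pd.Series(False, index=df.index)


def define_outcomes(df: pd.DataFrame):
    """Composite guideline outcomes as the OR of their criteria.

    diabetes: physician diagnosis, FBG >= 126 mg/dL, HbA1c >= 6.5 %, or
    anti-diabetic medication / insulin therapy.
    dyslipidemia: diagnosis, TCHOL >= 240, LDL >= 160, HDL <= 40,
    TG >= 200 mg/dL, or lipid-lowering medication.
    hypertension: diagnosis, SBP >= 140, DBP >= 90 mmHg, or medication.
    obesity: BMI >= 25 kg/m2; WC >= 90 cm (males) / >= 85 cm (females);
    WHtR >= 0.5.

    A record with at least one satisfied criterion is "yes" even when other
    components are missing; a record whose every component is missing gets a
    missing outcome (counts returned in the log).
    Returns ``(outcome frame, log dict)``.
    """
    crit = {
        "diabetes": [
            _flag(df, "dx_diabetes"), _flag(df, "med_diabetes"),
            _meas(df, "fbg", lambda v: v >= 126),
            _meas(df, "hba1c", lambda v: v >= 6.5),
        ],
        "dyslipidemia": [
            _flag(df, "dx_dyslipidemia"), _flag(df, "med_dyslipidemia"),
            _meas(df, "tchol", lambda v: v >= 240),
            _meas(df, "ldl", lambda v: v >= 160),
            _meas(df, "hdl", lambda v: v <= 40),
            _meas(df, "tg", lambda v: v >= 200),
        ],
        "hypertension": [
            _flag(df, "dx_hypertension"), _flag(df, "med_hypertension"),
            _meas(df, "sbp", lambda v: v >= 140),
            _meas(df, "dbp", lambda v: v >= 90),
        ],
        "obesity_bmi": [_meas(df, "bmi", lambda v: v >= 25)],
    }
    if {"wc", "sex"} <= set(df.columns):
        wc = pd.to_numeric(df["wc"], errors="raise")
        thr = np.where(df["sex"] == "M", 90.0, 85.0)
        crit["obesity_wc"] = [((wc >= thr).fillna(False), wc.notna())]
    else:
        crit["obesity_wc"] = [(pd.Series(False, index=df.index),
                               pd.Series(False, index=df.index))]
    if "whtr" in df.columns:
        crit["obesity_whtr"] = [_meas(df, "whtr", lambda v: v >= 0.5)]
    elif {"wc", "height"} <= set(df.columns):
        whtr = pd.to_numeric(df["wc"], errors="raise") / pd.to_numeric(
            df["height"], errors="raise")
        crit["obesity_whtr"] = [((whtr >= 0.5).fillna(False), whtr.notna())]
    else:
        crit["obesity_whtr"] = [(pd.Series(False, index=df.index),
                                 pd.Series(False, index=df.index))]

    out = pd.DataFrame(index=df.index)
    log = {}
    for name, pairs in crit.items():
        any_yes = pd.Series(False, index=df.index)
        any_obs = pd.Series(False, index=df.index)
        for yes, obs in pairs:
            any_yes |= yes
            any_obs |= obs
        col = pd.Series(
            pd.Categorical(np.where(any_yes, "yes", "no"), categories=list(YESNO)),
            index=df.index)
        col[~any_obs & ~any_yes] = None
        out[name] = col
        log[name] = {"missing": int((~any_obs & ~any_yes).sum())}
    return out, log


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

HISTORY_FLAGS = ("hx_cvd", "hx_cancer", "hx_kidney")


def apply_exclusions(
    df: pd.DataFrame,
    age_min: int = 40,
    age_max: int = 69,
    required: list | None = None,
):
    """Completeness -> age window -> disease-history exclusions, in order.

    ``required`` names the analysis columns for the complete-case step
    (default: every non-design column present).  A record matching several
    criteria is attributed to the first in the order.  Returns the retained
    frame and a per-criterion log.
    """
    log = []
    work = df

    if required is None:
        required = [c for c in df.columns if c not in ("weight", "stratum", "psu")]
    required = [c for c in required if c in df.columns]
    keep = work[required].notna().all(axis=1) if required else pd.Series(True, index=work.index)
    log.append({"criterion": "incomplete_survey_or_examination",
                "removed": int((~keep).sum()), "remaining": int(keep.sum())})
    work = work[keep]

    if "age" in work.columns:
        keep = (work["age"] >= age_min) & (work["age"] <= age_max)
    else:
        keep = pd.Series(True, index=work.index)
    log.append({"criterion": f"age_outside_{age_min}_{age_max}",
                "removed": int((~keep).sum()), "remaining": int(keep.sum())})
    work = work[keep]

    history = pd.Series(False, index=work.index)
    for col in HISTORY_FLAGS:
        if col in work.columns:
            history |= work[col] == "yes"
    keep = ~history
    log.append({"criterion": "cvd_cancer_or_kidney_history",
                "removed": int((~keep).sum()), "remaining": int(keep.sum())})
    work = work[keep]

    if len(work) == 0:
        raise EmptyCohortError("no records remain after exclusions")
    return work, log


def write_exclusion_log(log, path):
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Quartile binning
# ---------------------------------------------------------------------------

@dataclass
class QuartileGrouping:
    """Quartile cut points and the Q1..Q4 label of each input value.

    Labels: Q1 iff value <= q1; Q2 iff q1 < value <= q2; Q3 iff
    q2 < value <= q3; Q4 iff value > q3 (boundary values fall low).
    """

    cuts: tuple
    labels: pd.Categorical = field(repr=False)

    LEVELS = ("Q1", "Q2", "Q3", "Q4")

    def assign(self, values):
        values = np.asarray(values, dtype=float)
        idx = np.searchsorted(np.asarray(self.cuts), values, side="left")
        return pd.Categorical.from_codes(
            np.where(np.isnan(values), -1, idx).astype(int), categories=list(self.LEVELS))


def quartile_bin(values) -> QuartileGrouping:
    """Unweighted empirical quartile grouping of the analysis cohort.

    Cuts are linear-interpolation quantiles of the finite input values;
    survey weights are deliberately ignored for binning.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 4:
        raise DegenerateQuartileError("need >= 4 finite values for quartiles")
    q1, q2, q3 = np.quantile(finite, [0.25, 0.5, 0.75])
    if q1 == q3:
        raise DegenerateQuartileError("quartile cuts are degenerate (q1 == q3)")
    grouping = QuartileGrouping(cuts=(float(q1), float(q2), float(q3)), labels=None)
    grouping.labels = grouping.assign(arr)
    return grouping


# ---------------------------------------------------------------------------
# High-level derivation
# ---------------------------------------------------------------------------

AGE_GROUPS = ((40, "40-49"), (50, "50-59"), (60, "60-69"))


def derive_cohort(df: pd.DataFrame, quartile_targets=("homa_ir", "tyg", "tg_hdl"),
                  overwrite: bool = False):
    """Full derivation pass: LDL fill-in, indices, categories, outcomes,
    quartile groups.  Returns ``(derived frame, info dict)``.

    Columns already present are kept unless ``overwrite=True`` (a cohort
    sampled with its categorical states attached keeps them; raw user data
    gets everything derived from the labs).
    """
    out = df.copy()
    info = {}

    def want(col):
        return overwrite or col not in out.columns

    if {"tchol", "hdl", "tg"} <= set(out.columns):
        est = friedewald_ldl(out["tchol"], out["hdl"], out["tg"])
        if "ldl" in out.columns:
            fill = out["ldl"].isna()
            out.loc[fill, "ldl"] = est[fill.to_numpy()]
            info["ldl_friedewald_filled"] = int(fill.sum())
        else:
            out["ldl"] = est
            info["ldl_friedewald_filled"] = int(len(out))
        neg = out["ldl"] < 0
        out["ldl_friedewald_negative"] = np.where(neg, "yes", "no")
        info["ldl_friedewald_negative"] = int(neg.sum())
    if {"wc", "height"} <= set(out.columns) and want("whtr"):
        out["whtr"] = out["wc"] / out["height"]
    if "age" in out.columns and want("age_group"):
        labels = [lab for _, lab in AGE_GROUPS]
        out["age_group"] = pd.cut(out["age"], bins=[40, 50, 60, 70], right=False,
                                  labels=labels)
    if {"fbg", "tg", "hdl"} <= set(out.columns):
        insulin = out["insulin"] if "insulin" in out.columns else np.full(len(out), np.nan)
        idx = compute_indices(insulin, out["fbg"], out["tg"], out["hdl"])
        idx.index = out.index
        for c in idx.columns:
            if want(c):
                out[c] = idx[c]
    cats = categorize_clinical(out)
    for c in cats.columns:
        if c not in out.columns or overwrite:
            out[c] = cats[c]
        elif c.endswith("_cat") or c in ("sleep", "drinking", "smoking"):
            out[c] = cats[c]  # recategorization is idempotent by construction
    outcomes, outcome_log = define_outcomes(out)
    for c in outcomes.columns:
        if want(c):
            out[c] = outcomes[c]
    info["outcomes"] = outcome_log
    for col in quartile_targets:
        if col in out.columns and want(f"{col}_q") and out[col].notna().sum() >= 4:
            grouping = quartile_bin(out[col])
            out[f"{col}_q"] = grouping.labels
            info[f"{col}_cuts"] = grouping.cuts
    return out, info


# ---------------------------------------------------------------------------
# Default codebook
# ---------------------------------------------------------------------------

def default_codebook() -> Codebook:
    """Registry of the analysis variables with their declared levels."""
    c, o = "categorical", "outcome"
    nd = ("Normal", "Danger")
    ncd = ("Normal", "Caution", "Danger")
    entries = [
        VariableSpec("age", "continuous", units="years"),
        VariableSpec("sex", c, ("M", "F")),
        VariableSpec("age_group", c, ("40-49", "50-59", "60-69")),
        VariableSpec("education", c, ("<=Middle", "High", ">=College")),
        VariableSpec("sleep", c, BEHAVIOR_LEVELS["sleep"]),
        VariableSpec("drinking", c, BEHAVIOR_LEVELS["drinking"]),
        VariableSpec("smoking", c, BEHAVIOR_LEVELS["smoking"]),
        VariableSpec("muscle_activity", c, YESNO),
        VariableSpec("insulin", "continuous", units="uIU/mL"),
        VariableSpec("fbg", "continuous", units="mg/dL"),
        VariableSpec("tg", "continuous", units="mg/dL"),
        VariableSpec("hdl", "continuous", units="mg/dL"),
        VariableSpec("tchol", "continuous", units="mg/dL"),
        VariableSpec("ldl", "continuous", units="mg/dL", derivation="friedewald"),
        VariableSpec("hba1c", "continuous", units="%"),
        VariableSpec("sbp", "continuous", units="mmHg"),
        VariableSpec("dbp", "continuous", units="mmHg"),
        VariableSpec("bmi", "continuous", units="kg/m2"),
        VariableSpec("wc", "continuous", units="cm"),
        VariableSpec("height", "continuous", units="cm"),
        VariableSpec("sbp_cat", c, ncd, derivation="band"),
        VariableSpec("dbp_cat", c, ncd, derivation="band"),
        VariableSpec("fbg_cat", c, ncd, derivation="band"),
        VariableSpec("hba1c_cat", c, ncd, derivation="band"),
        VariableSpec("tg_cat", c, ncd, derivation="band"),
        VariableSpec("tchol_cat", c, ncd, derivation="band"),
        VariableSpec("ldl_cat", c, ncd, derivation="band"),
        VariableSpec("hdl_cat", c, nd, derivation="band"),
        VariableSpec("homa_ir", "continuous", derivation="insulin*fbg/405"),
        VariableSpec("tyg", "continuous", derivation="ln(tg*fbg/2)"),
        VariableSpec("tg_hdl", "continuous", derivation="tg/hdl"),
        VariableSpec("homa_ir_q", c, QuartileGrouping.LEVELS, derivation="quartile"),
        VariableSpec("tyg_q", c, QuartileGrouping.LEVELS, derivation="quartile"),
        VariableSpec("tg_hdl_q", c, QuartileGrouping.LEVELS, derivation="quartile"),
        VariableSpec("diabetes", o, YESNO),
        VariableSpec("dyslipidemia", o, YESNO),
        VariableSpec("hypertension", o, YESNO),
        VariableSpec("obesity_bmi", o, YESNO),
        VariableSpec("obesity_wc", o, YESNO),
        VariableSpec("obesity_whtr", o, YESNO),
        VariableSpec("weight", "design"),
        VariableSpec("stratum", "design"),
        VariableSpec("psu", "design"),
    ]
    return Codebook(entries)
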
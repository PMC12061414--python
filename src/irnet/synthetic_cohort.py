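"""Synthetic KNHANES-like cohort generator with known ground truth.

Cohorts are drawn by ancestral sampling from a fully specified discrete
Bayesian network over the analysis variables (demographics, behaviours,
clinical categories, the three IR-index quartile variables and the two
outcomes), so that structure-learning and inference stages can be tested
against a known graph.  A separate emission step adds raw continuous labs
and anthropometrics that are *bin-consistent* with the sampled categorical
states, letting the clinical derivation rules be exercised end-to-end.

The default network encodes the qualitative metabolic structure of a
Korean adult cohort aged 40-69: the index chain TG/HDL ratio -> TyG -> HOMA-IR, fasting
glucose as a parent of all three indices and a child of diabetes, the
lipid panel and age as parents of dyslipidemia, and obesity indicators
adjacent to HOMA-IR.  Conditional distributions are deliberately strong so
that structure recovery from realistic sample sizes is feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .bn_inference import FittedBN, _ancestral_sample
from .bn_structure import DAG

__all__ = [
    "GroundTruthSpec",
    "korean_cohort_spec",
    "sample_cohort",
    "emit_continuous",
    "arc_shift_strength",
]


# ---------------------------------------------------------------------------
# Ground-truth specification
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthSpec:
    """A known DAG + CPTs + survey-design model for cohort simulation.

    ``cpts[node] = {"parents": sorted list, "table": (q, r) array}`` with
    the mixed-radix row convention of :class:`irnet.bn_inference.FittedBN`
    (most significant parent first).  Survey weights are drawn independent
    of all variables by default (mean 1), so weighted and unweighted
    analyses agree asymptotically; ``informative_weights`` ties them to age
    and sex for sensitivity testing.
    """

    levels: dict
    cpts: dict
    weight_sigma: float = 0.4
    informative_weights: bool = False
    n_strata: int = 17
    psus_per_stratum: int = 20
    name: str = "ground_truth"

    def __post_init__(self):
        for node, spec in self.cpts.items():
            table = np.asarray(spec["table"], dtype=float)
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {node!r} must sum to 1 within 1e-12")
            spec["table"] = table
        self.dag()  # raises if cyclic

    def dag(self) -> DAG:
        arcs = [(p, n) for n, spec in self.cpts.items() for p in spec["parents"]]
        return DAG(list(self.levels), arcs)

    def to_fitted_bn(self) -> FittedBN:
        return FittedBN(
            dag=self.dag(),
            levels={n: list(v) for n, v in self.levels.items()},
            cpts={n: s["table"] for n, s in self.cpts.items()},
            parent_order={n: list(s["parents"]) for n, s in self.cpts.items()},
        ).validate(tol=1e-9)

    # structured-text serialization
    def to_yaml(self, path):
        payload = {
            "name": self.name,
            "levels": {n: list(v) for n, v in self.levels.items()},
            "cpts": {n: {"parents": list(s["parents"]),
                         "table": np.asarray(s["table"]).tolist()}
                     for n, s in self.cpts.items()},
            "weight_sigma": self.weight_sigma,
            "informative_weights": self.informative_weights,
            "n_strata": self.n_strata,
            "psus_per_stratum": self.psus_per_stratum,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(levels=d["levels"], cpts=d["cpts"],
                   weight_sigma=d["weight_sigma"],
                   informative_weights=d["informative_weights"],
                   n_strata=d["n_strata"], psus_per_stratum=d["psus_per_stratum"],
                   name=d.get("name", "ground_truth"))


def _build_cpt(levels: dict, parents, fn):
    """Tabulate ``fn(config dict) -> prob vector`` over sorted parents."""
    parents = sorted(parents)
    cards = [len(levels[p]) for p in parents]
    q = int(np.prod(cards)) if parents else 1
    rows = []
    for flat in range(q):
        cfg, rem = {}, flat
        for p, c in zip(reversed(parents), reversed(cards)):
            cfg[p] = levels[p][rem % c]
            rem //= c
        row = np.asarray(fn(cfg), dtype=float)
        rows.append(row / row.sum())
    return {"parents": parents, "table": np.vstack(rows)}


def _ordinal_softmax(levels, node, parents, betas):
    """Monotone ordinal dependence: p_k ~ exp(s_k * sum_p beta_p * u_p).

    ``s_k`` spreads the child levels over [-1.5, 1.5]; each parent
    contributes its scaled level ``u_p`` in [-1, 1] times ``beta_p``.
    """
    r = len(levels[node])
    s = np.linspace(-1.5, 1.5, r)

    def u(p, lev):
        rp = len(levels[p])
        return np.linspace(-1.0, 1.0, rp)[levels[p].index(lev)]

    def fn(cfg):
        eta = sum(betas[p] * u(p, lev) for p, lev in cfg.items())
        w = np.exp(s * eta)
        return w / w.sum()

    return _build_cpt(levels, parents, fn)


def korean_cohort_spec(seed: int = 0, informative_weights: bool = False,
                       behavior_index_arcs: bool = False) -> GroundTruthSpec:
    """The default ground truth for a Korean-adult-like metabolic cohort.

    The DAG contains the sequential index chain (TG/HDL ratio -> TyG ->
    HOMA-IR), FBG as parent of all three indices and child of diabetes,
    the lipid variables and age as parents of dyslipidemia, obesity
    indicators as children of HOMA-IR (so they sit in its Markov blanket),
    and behaviour/demographic arcs.  CPT rows that would contradict the
    outcome definitions carry zero mass (e.g. fasting glucose cannot be in
    the Danger band without diabetes, and a Danger-band lipid forces
    dyslipidemia), matching the structural zeros of the descriptive tables.

    ``seed`` is accepted for interface uniformity; the specification is
    deterministic.
    """
    del seed
    lv = {
        "sex": ["M", "F"],
        "age_group": ["40-49", "50-59", "60-69"],
        "education": ["<=Middle", "High", ">=College"],
        "smoking": ["no", "yes"],
        "drinking": ["<1/mo", ">=1/mo"],
        "muscle_activity": ["no", "yes"],
        "diabetes": ["no", "yes"],
        "dyslipidemia": ["no", "yes"],
        "hypertension": ["no", "yes"],
        "fbg_cat": ["Normal", "Caution", "Danger"],
        "tg_cat": ["Normal", "Caution", "Danger"],
        "hdl_cat": ["Normal", "Danger"],
        "tchol_cat": ["Normal", "Caution", "Danger"],
        "ldl_cat": ["Normal", "Caution", "Danger"],
        "obesity_bmi": ["no", "yes"],
        "obesity_wc": ["no", "yes"],
        "obesity_whtr": ["no", "yes"],
        "tg_hdl_q": ["Q1", "Q2", "Q3", "Q4"],
        "tyg_q": ["Q1", "Q2", "Q3", "Q4"],
        "homa_ir_q": ["Q1", "Q2", "Q3", "Q4"],
    }

    def root(node, probs):
        return {"parents": [], "table": np.asarray([probs], dtype=float)}

    def rows(node, parents, mapping):
        return _build_cpt(lv, parents, lambda cfg: mapping[tuple(cfg[p] for p in sorted(parents))])

    cpts = {
        "sex": root("sex", [0.5, 0.5]),
        "age_group": root("age_group", [0.37, 0.37, 0.26]),
        "muscle_activity": root("muscle_activity", [0.74, 0.26]),
        "tg_cat": root("tg_cat", [0.60, 0.20, 0.20]),
        "hdl_cat": root("hdl_cat", [0.80, 0.20]),
        "tchol_cat": root("tchol_cat", [0.52, 0.34, 0.14]),
        "education": rows("education", ["age_group"], {
            ("40-49",): [0.06, 0.30, 0.64],
            ("50-59",): [0.20, 0.48, 0.32],
            ("60-69",): [0.52, 0.32, 0.16],
        }),
        "smoking": rows("smoking", ["sex"], {
            ("M",): [0.55, 0.45], ("F",): [0.93, 0.07]}),
        "drinking": rows("drinking", ["sex"], {
            ("M",): [0.25, 0.75], ("F",): [0.60, 0.40]}),
        "diabetes": rows("diabetes", ["age_group"], {
            ("40-49",): [0.97, 0.03],
            ("50-59",): [0.72, 0.28],
            ("60-69",): [0.44, 0.56],
        }),
        # structural zero: Danger FBG implies diabetes by definition
        "fbg_cat": rows("fbg_cat", ["diabetes"], {
            ("no",): [0.66, 0.34, 0.0],
            ("yes",): [0.04, 0.38, 0.58],
        }),
        "ldl_cat": rows("ldl_cat", ["tchol_cat"], {
            ("Normal",): [0.88, 0.11, 0.01],
            ("Caution",): [0.45, 0.48, 0.07],
            ("Danger",): [0.10, 0.55, 0.35],
        }),
        "tg_hdl_q": _ordinal_softmax(
            lv, "tg_hdl_q",
            ["fbg_cat", "tg_cat", "hdl_cat"] + (
                ["muscle_activity"] if behavior_index_arcs else []),
            {"fbg_cat": 1.2, "tg_cat": 1.6, "hdl_cat": 1.4, "muscle_activity": -0.6}),
        "tyg_q": _ordinal_softmax(
            lv, "tyg_q",
            ["fbg_cat", "tg_hdl_q"] + (
                ["smoking", "drinking"] if behavior_index_arcs else []),
            {"fbg_cat": 1.2, "tg_hdl_q": 1.6, "smoking": 0.7, "drinking": 0.7}),
        "homa_ir_q": _ordinal_softmax(
            lv, "homa_ir_q",
            ["tyg_q", "fbg_cat"] + (["age_group"] if behavior_index_arcs else []),
            {"tyg_q": 1.6, "fbg_cat": 1.0, "age_group": 0.7}),
    }

    def bern(p):
        return [1.0 - p, p]

    q_yes = {"Q1": 0.10, "Q2": 0.36, "Q3": 0.62, "Q4": 0.88}
    cpts["obesity_bmi"] = rows("obesity_bmi", ["homa_ir_q"],
                               {(q,): bern(p) for q, p in q_yes.items()})
    q_yes_wc = {"Q1": 0.08, "Q2": 0.34, "Q3": 0.60, "Q4": 0.86}
    cpts["obesity_wc"] = rows("obesity_wc", ["homa_ir_q"],
                              {(q,): bern(p) for q, p in q_yes_wc.items()})
    q_yes_whtr = {"Q1": 0.15, "Q2": 0.42, "Q3": 0.68, "Q4": 0.93}
    cpts["obesity_whtr"] = rows("obesity_whtr", ["homa_ir_q"],
                                {(q,): bern(p) for q, p in q_yes_whtr.items()})

    def htn(cfg):
        base = {"40-49": 0.12, "50-59": 0.38, "60-69": 0.63}[cfg["age_group"]]
        if cfg["obesity_bmi"] == "yes":
            base += 0.27
        return bern(min(base, 0.97))

    cpts["hypertension"] = _build_cpt(lv, ["age_group", "obesity_bmi"], htn)

    def dyslip(cfg):
        # a Danger-band lipid meets the outcome definition outright
        if (cfg["tg_cat"] == "Danger" or cfg["hdl_cat"] == "Danger"
                or cfg["tchol_cat"] == "Danger" or cfg["ldl_cat"] == "Danger"):
            return [0.0, 1.0]
        p = 0.08
        if cfg["tg_cat"] == "Caution":
            p += 0.30
        if cfg["tchol_cat"] == "Caution":
            p += 0.28
        if cfg["ldl_cat"] == "Caution":
            p += 0.28
        p += {"40-49": 0.0, "50-59": 0.27, "60-69": 0.54}[cfg["age_group"]]
        return bern(min(p, 0.97))

    cpts["dyslipidemia"] = _build_cpt(
        lv, ["tg_cat", "hdl_cat", "tchol_cat", "ldl_cat", "age_group"], dyslip)

    return GroundTruthSpec(levels=lv, cpts=cpts,
                           informative_weights=informative_weights)


def arc_shift_strength(spec: GroundTruthSpec) -> pd.DataFrame:
    """Per-arc dependence strength of the ground-truth CPTs.

    For each arc p -> c: the maximum, over configurations of the other
    parents, of the total-variation distance between the child conditionals
    at adjacent levels of p.  Used to verify that every encoded dependence
    is strong enough to be recoverable.
    """
    rows = []
    for child, s in spec.cpts.items():
        parents = s["parents"]
        if not parents:
            continue
        cards = [len(spec.levels[p]) for p in parents]
        table = s["table"].reshape(cards + [-1])
        for ax, p in enumerate(parents):
            t = np.moveaxis(table, ax, 0)
            tv = 0.5 * np.abs(np.diff(t, axis=0)).sum(axis=-1)
            rows.append({"parent": p, "child": child,
                         "max_adjacent_tv": float(tv.max()),
                         "mean_adjacent_tv": float(tv.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ancestral sampling
# ---------------------------------------------------------------------------

def sample_cohort(spec: GroundTruthSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` records by ancestral sampling; attach survey design.

    Identical ``(spec, n, seed)`` produce bit-identical tables.  Weights
    have mean 1; PSU labels nest within strata by construction.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    fbn = spec.to_fitted_bn()
    cols = {}
    if n > 0:
        samples, _ = _ancestral_sample(fbn, n, rng)
        for node in spec.levels:
            cols[node] = pd.Categorical.from_codes(
                samples[node], categories=list(spec.levels[node]))
    else:
        for node in spec.levels:
            cols[node] = pd.Categorical([], categories=list(spec.levels[node]))
    df = pd.DataFrame(cols)
    df.index.name = "id"

    strata = rng.integers(0, spec.n_strata, size=n)
    psus = rng.integers(0, spec.psus_per_stratum, size=n)
    df["stratum"] = [f"S{h:02d}" for h in strata]
    df["psu"] = [f"S{h:02d}-P{j:02d}" for h, j in zip(strata, psus)]

    w = np.exp(rng.normal(0.0, spec.weight_sigma, size=n))
    if spec.informative_weights and n > 0:
        w = w * (1.0 + 0.35 * (df["sex"] == "F").to_numpy()
                 + 0.25 * (df["age_group"] == "60-69").to_numpy())
    if n > 0:
        w = w / w.mean()
    df["weight"] = w
    return df


# ---------------------------------------------------------------------------
# Continuous emission
# ---------------------------------------------------------------------------

def _trunc_lognormal(rng, lo, hi, size, sigma=0.35):
    """Log-normal draws truncated to [lo, hi)."""
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (size,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (size,))
    mu = 0.5 * (np.log(lo) + np.log(hi))
    a = ndtr((np.log(lo) - mu) / sigma)
    b = ndtr((np.log(hi) - mu) / sigma)
    u = a + rng.random(size) * (b - a)
    x = np.exp(mu + sigma * ndtri(u))
    return np.clip(x, lo, hi - 1e-9)


# per category: [lo, hi) emission band, matching the clinical cut-offs
EMIT_BINS = {
    "fbg_cat": ("fbg", {"Normal": (72, 100), "Caution": (100, 126), "Danger": (126, 240)}),
    "tg_cat": ("tg", {"Normal": (45, 150), "Caution": (150, 200), "Danger": (200, 560)}),
    "hdl_cat": ("hdl", {"Normal": (41, 110), "Danger": (22, 40)}),
    "tchol_cat": ("tchol", {"Normal": (125, 200), "Caution": (200, 240), "Danger": (240, 350)}),
    "ldl_cat": ("ldl", {"Normal": (55, 130), "Caution": (130, 190), "Danger": (190, 275)}),
}

# ground-truth continuous bands for the index quartile nodes (the reported
# population cut points)
INDEX_BINS = {
    "tyg_q": ("tyg", (7.2, 8.22, 8.66, 9.11, 10.6)),
    "homa_ir_q": ("homa_ir", (0.30, 1.15, 1.75, 2.79, 12.0)),
    "tg_hdl_q": ("tg_hdl", (0.25, 1.37, 2.27, 3.83, 16.0)),
}


def _by_level(df, node, rng, bands, sigma=0.35):
    vals = np.empty(len(df))
    codes = df[node]
    for lev, (lo, hi) in bands.items():
        m = (codes == lev).to_numpy()
        if m.any():
            vals[m] = _trunc_lognormal(rng, lo, hi, int(m.sum()), sigma)
    return vals


def emit_continuous(cohort: pd.DataFrame, spec: GroundTruthSpec, seed: int) -> pd.DataFrame:
    """Add raw labs, anthropometrics and diagnosis flags to a sampled cohort.

    Emitted values land inside the band of their sampled categorical state,
    so re-categorizing with the clinical rules reproduces the sampled state
    exactly, and re-deriving the composite outcomes reproduces the sampled
    outcome nodes exactly (physician-diagnosis flags are set whenever an
    outcome is "yes" but no emitted lab criterion fires).  Insulin is
    back-solved from the HOMA-IR band so the HOMA-IR formula round-trips;
    the TyG and TG/HDL continuous columns are emitted from their own bands
    and are *not* constrained to equal the recomputed values from the
    emitted labs (see the package methods note).
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)

    # age consistent with its decade group
    dec = {"40-49": 40, "50-59": 50, "60-69": 60}
    base = out["age_group"].map(dec).astype(float).to_numpy()
    out["age"] = np.floor(base + rng.random(n) * 10).astype(int)

    for node, (col, bands) in EMIT_BINS.items():
        out[col] = _by_level(out, node, rng, bands)
    # dyslipidemia "no" caps LDL below the 160 mg/dL outcome threshold
    cap = ((out["dyslipidemia"] == "no") & (out["ldl_cat"] == "Caution")).to_numpy()
    if cap.any():
        out.loc[cap, "ldl"] = _trunc_lognormal(rng, 130, 160, int(cap.sum()))
    # total cholesterol never below HDL (Friedewald domain)
    out["tchol"] = np.maximum(out["tchol"], out["hdl"] + 5.0)

    # continuous index values inside the ground-truth quartile bands
    for node, (col, edges) in INDEX_BINS.items():
        bands = {q: (edges[i], edges[i + 1]) for i, q in
                 enumerate(spec.levels[node])}
        out[col] = _by_level(out, node, rng, bands, sigma=0.25)
    out["insulin"] = out["homa_ir"] * 405.0 / out["fbg"]

    # HbA1c: below the diagnostic threshold unless diabetic with Danger FBG
    hb = _trunc_lognormal(rng, 4.8, 6.4, n, sigma=0.1)
    danger = (out["fbg_cat"] == "Danger").to_numpy()
    hb[danger] = _trunc_lognormal(rng, 6.5, 9.5, int(danger.sum()), sigma=0.2)
    out["hba1c"] = hb

    # blood pressure consistent with the hypertension node
    htn = (out["hypertension"] == "yes").to_numpy()
    sbp = _trunc_lognormal(rng, 95, 140, n, sigma=0.12)
    dbp = _trunc_lognormal(rng, 60, 90, n, sigma=0.12)
    sbp[htn] = _trunc_lognormal(rng, 120, 185, int(htn.sum()), sigma=0.15)
    dbp[htn] = _trunc_lognormal(rng, 70, 105, int(htn.sum()), sigma=0.15)
    out["sbp"], out["dbp"] = sbp, dbp

    # anthropometrics: BMI and WC from their obesity nodes, height chosen so
    # WHtR falls on the right side of 0.5
    out["bmi"] = _by_level(out, "obesity_bmi", rng, {"no": (19, 25), "yes": (25, 36)})
    male = (out["sex"] == "M").to_numpy()
    wc_lo = np.where((out["obesity_wc"] == "yes").to_numpy(),
                     np.where(male, 90.0, 85.0), np.where(male, 74.0, 73.5))
    wc_hi = np.where((out["obesity_wc"] == "yes").to_numpy(),
                     np.where(male, 97.0, 95.0), np.where(male, 90.0, 85.0))
    out["wc"] = _trunc_lognormal(rng, wc_lo, wc_hi, n, sigma=0.08)
    high_whtr = (out["obesity_whtr"] == "yes").to_numpy()
    h_lo = np.where(high_whtr, 146.0, 2 * out["wc"] + 0.5)
    h_hi = np.where(high_whtr, 2 * out["wc"] - 0.5, 198.0)
    out["height"] = _trunc_lognormal(rng, h_lo, h_hi, n, sigma=0.05)

    # behaviours backing the categorical recodes
    out["sleep_hours"] = np.round(4.5 + rng.random(n) * 4.5, 1)
    out["drink_freq"] = np.where(out["drinking"] == ">=1/mo",
                                 1 + rng.integers(0, 20, n), 0)
    out["smoked_ge5packs"] = out["smoking"].astype(str)
    out["current_smoker"] = "no"

    # diagnosis flags close the gap between outcome nodes and lab criteria
    dia_lab = (out["fbg"] >= 126) | (out["hba1c"] >= 6.5)
    out["dx_diabetes"] = np.where((out["diabetes"] == "yes") & ~dia_lab, "yes", "no")
    dys_lab = ((out["tchol"] >= 240) | (out["ldl"] >= 160) | (out["hdl"] <= 40)
               | (out["tg"] >= 200))
    out["dx_dyslipidemia"] = np.where(
        (out["dyslipidemia"] == "yes") & ~dys_lab, "yes", "no")
    htn_lab = (out["sbp"] >= 140) | (out["dbp"] >= 90)
    out["dx_hypertension"] = np.where(
        (out["hypertension"] == "yes") & ~htn_lab, "yes", "no")
    for c in ("med_diabetes", "med_dyslipidemia", "med_hypertension",
              "hx_cvd", "hx_cancer", "hx_kidney"):
        out[c] = "no"
    return out
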
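"""Synthetic survey generator for the hybrid choice analysis.

Draws respondents (binary/categorical covariates at the study's observed
proportions), three latent psychological constructs via a recursive
structural model, five-point Likert indicators via ordered logit, and panel
choices over six experimental tasks plus one dominance QC task, all from a
known parameter set.  Latent constructs:

    HR  (health-risk perceptions)   = gamma_HR  . z + eta1
    AW  (scheme awareness)          = gamma_AW  . z + lam_hr_aw * HR + eta2
    VAL (perceived scheme value)    = gamma_VAL . z + lam_hr_val * HR
                                      + lam_aw_val * AW + eta3

with eta ~ N(0,1) iid, z the six structural covariates (gender, two age
bands, residence, catastrophic-disease experience, prior private insurance).

Insurance-alternative utility for respondent n, coded attribute vector x:

    V = sum_k (b_k + sigma_k xi_nk) x_k + sum_k (theta_k . [HR,AW,VAL,z]) x_k
    V_optout = delta + phi_HR HR + phi_AW AW + phi_VAL VAL

xi ~ N(0,1) drawn once per respondent (panel), choices are MNL (iid Gumbel).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import (
    ChoiceDesign,
    code_profile,
    coded_columns,
    is_dominated,
)

# structural covariates, in the order used by gamma vectors and interactions
STRUCTURAL_COVARIATES = [
    "gender",
    "age_mid",
    "age_old",
    "residence",
    "catastrophic",
    "private_insurance",
]
# extra sampled covariates not entering the structural/choice models
EXTRA_COVARIATES = ["education", "income"]

CONSTRUCTS = ["HR", "AW", "VAL"]
INDICATORS = [
    ("hr1", "HR"), ("hr2", "HR"), ("hr3", "HR"), ("hr4", "HR"), ("hr5", "HR"),
    ("aw1", "AW"), ("aw2", "AW"), ("aw3", "AW"),
    ("val1", "VAL"), ("val2", "VAL"), ("val3", "VAL"),
]
INDICATOR_NAMES = [n for n, _ in INDICATORS]

# variables that may interact with attribute levels: 3 latents + 6 covariates
INTERACTION_VARIABLES = CONSTRUCTS + STRUCTURAL_COVARIATES

# coded attribute columns that carry random coefficients (all but the
# moderate-involvement dummy, whose taste variation was negligible)
RANDOM_SLOTS = [
    "premium",
    "government:strong",
    "deductible",
    "reimbursement",
    "value_added:expanded1",
    "value_added:expanded2",
    "value_added:expanded3",
]

DEFAULT_PROPORTIONS = {
    "gender": 0.514,            # 1 = female
    "residence": 0.707,         # 1 = urban
    "age_bands": (0.210, 0.510, 0.281),  # 18-34 (ref) / 35-59 / 60-75
    "education": 0.204,         # 1 = college or above
    "income": 0.306,            # 1 = above average
    "private_insurance": 0.467,
    "catastrophic": 0.1699,
}

DEFAULT_AGE_BAND_LABELS = ("18-34", "35-59", "60-75")


@dataclass
class HCMParameterSet:
    """Every estimable quantity of the hybrid choice model.

    gamma_* are weights on ``STRUCTURAL_COVARIATES``; ``zeta``/``tau`` are the
    ordered-logit loadings and (strictly increasing) thresholds of the 11
    Likert indicators; ``b``/``sigma`` the choice means and taste SDs on the
    coded attribute columns; ``theta`` maps (random attribute slot,
    interaction variable) -> mean shift; ``delta``/``phi`` the opt-out ASC
    and its latent shifts.  ``provenance`` records, per field, whether the
    default came from a published estimate or is a documented default.
    """

    gamma_HR: np.ndarray
    gamma_AW: np.ndarray
    gamma_VAL: np.ndarray
    lam_hr_aw: float
    lam_hr_val: float
    lam_aw_val: float
    zeta: np.ndarray               # (11,)
    tau: np.ndarray                # (11, 4), strictly increasing rows
    b: dict                        # coded column -> mean
    sigma: dict                    # random slot -> SD (stored unsigned)
    theta: dict                    # (slot, variable) -> coefficient
    delta: float
    phi: dict                      # construct -> opt-out shift
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gamma_HR = np.asarray(self.gamma_HR, float)
        self.gamma_AW = np.asarray(self.gamma_AW, float)
        self.gamma_VAL = np.asarray(self.gamma_VAL, float)
        self.zeta = np.asarray(self.zeta, float)
        self.tau = np.asarray(self.tau, float)
        if self.tau.shape != (len(INDICATORS), 4):
            raise ValueError("tau must be (11, 4)")
        if np.any(np.diff(self.tau, axis=1) <= 0):
            bad = int(np.where(np.any(np.diff(self.tau, axis=1) <= 0, axis=1))[0][0])
            raise ValueError(f"thresholds not strictly increasing for indicator {INDICATOR_NAMES[bad]}")
        self.sigma = {k: abs(float(v)) for k, v in self.sigma.items()}

    def to_dict(self) -> dict:
        return {
            "gamma_HR": self.gamma_HR.tolist(),
            "gamma_AW": self.gamma_AW.tolist(),
            "gamma_VAL": self.gamma_VAL.tolist(),
            "lam_hr_aw": self.lam_hr_aw,
            "lam_hr_val": self.lam_hr_val,
            "lam_aw_val": self.lam_aw_val,
            "zeta": self.zeta.tolist(),
            "tau": self.tau.tolist(),
            "b": dict(self.b),
            "sigma": dict(self.sigma),
            "theta": {f"{k[0]}|{k[1]}": v for k, v in self.theta.items()},
            "delta": self.delta,
            "phi": dict(self.phi),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HCMParameterSet":
        d = dict(d)
        d["theta"] = {tuple(k.split("|")): v for k, v in d["theta"].items()}
        d.pop("provenance", None)
        return cls(**d)


def default_true_params() -> HCMParameterSet:
    """Parameter set populated from the study's published point estimates.

    Thresholds (tau) and the non-significant interaction terms are documented
    defaults (the published tables print neither): tau = (-2, -0.5, 0.5, 2)
    for every indicator, omitted interactions 0.
    """
    published = "published estimate"
    default = "documented default"
    theta = {
        ("premium", "AW"): 0.003,
        ("premium", "residence"): -0.004,
        ("premium", "catastrophic"): 0.003,
        ("government:strong", "HR"): -0.178,
        ("government:strong", "residence"): 0.210,
        ("deductible", "HR"): -0.027,
        ("deductible", "gender"): 0.032,
        ("deductible", "residence"): -0.027,
        ("reimbursement", "HR"): 0.008,
        ("reimbursement", "AW"): -0.005,
        ("reimbursement", "gender"): -0.02,
        ("reimbursement", "age_mid"): -0.009,
        ("reimbursement", "age_old"): -0.007,
        ("reimbursement", "catastrophic"): -0.006,
        ("reimbursement", "private_insurance"): 0.006,
        ("value_added:expanded1", "HR"): 0.254,
        ("value_added:expanded1", "AW"): 0.210,
        ("value_added:expanded1", "VAL"): -0.200,
        ("value_added:expanded1", "private_insurance"): 0.271,
        ("value_added:expanded2", "HR"): 0.137,
        ("value_added:expanded3", "residence"): -0.419,
    }
    params = HCMParameterSet(
        gamma_HR=[-0.086, 0.263, 0.358, 0.106, 0.219, 0.126],
        gamma_AW=[0.088, -0.292, -0.665, 0.041, -0.104, 1.048],
        gamma_VAL=[-0.035, -0.073, 0.113, -0.125, 0.113, -0.063],
        lam_hr_aw=0.091,
        lam_hr_val=0.190,
        lam_aw_val=0.528,
        zeta=[1.629, 1.301, 1.566, 1.313, 1.306, 4.227, 1.287, 1.546, 2.665, 1.975, 1.882],
        tau=np.tile([-2.0, -0.5, 0.5, 2.0], (len(INDICATORS), 1)),
        b={
            "premium": -0.007,
            "government:moderate": 0.764,
            "government:strong": 0.880,
            "deductible": -0.036,
            "reimbursement": 0.049,
            "value_added:expanded1": 0.604,
            "value_added:expanded2": 0.742,
            "value_added:expanded3": 0.899,
        },
        sigma={
            "premium": 0.010,
            "government:strong": 0.641,
            "deductible": 0.110,
            "reimbursement": 0.03,
            "value_added:expanded1": 0.328,
            "value_added:expanded2": 0.848,
            "value_added:expanded3": 0.246,
        },
        theta=theta,
        delta=-3.889,
        phi={"HR": 0.125, "AW": 0.170, "VAL": -0.004},
    )
    params.provenance = {
        "gamma_HR": published, "gamma_AW": published, "gamma_VAL": published,
        "lam_hr_aw": published, "lam_hr_val": published, "lam_aw_val": published,
        "zeta": published, "tau": default,
        "b": published, "sigma": published,
        "theta": published + " (printed significant terms; remainder 0, " + default + ")",
        "delta": published, "phi": published,
    }
    return params


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_covariates(
    n: int,
    proportions: dict | None = None,
    seed: int = 0,
    age_band_labels=DEFAULT_AGE_BAND_LABELS,
) -> pd.DataFrame:
    """Independent Bernoulli/categorical covariate draws at stated proportions."""
    props = dict(DEFAULT_PROPORTIONS)
    if proportions:
        props.update(proportions)
    bands = np.asarray(props["age_bands"], float)
    # printed percentages may round to slightly off 1; renormalize within 2%
    if bands.min() < 0 or not np.isclose(bands.sum(), 1.0, atol=0.02):
        raise ValueError("age_bands: probabilities must be nonnegative and sum to 1")
    bands = bands / bands.sum()
    for fld in ("gender", "residence", "education", "income", "private_insurance", "catastrophic"):
        p = props[fld]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{fld}: probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    band_draw = rng.choice(3, size=n, p=bands)
    df = pd.DataFrame(
        {
            "respondent": np.arange(1, n + 1),
            "gender": (rng.random(n) < props["gender"]).astype(int),
            "age_mid": (band_draw == 1).astype(int),
            "age_old": (band_draw == 2).astype(int),
            "residence": (rng.random(n) < props["residence"]).astype(int),
            "education": (rng.random(n) < props["education"]).astype(int),
            "income": (rng.random(n) < props["income"]).astype(int),
            "private_insurance": (rng.random(n) < props["private_insurance"]).astype(int),
            "catastrophic": (rng.random(n) < props["catastrophic"]).astype(int),
        }
    )
    df["age_band"] = np.asarray(age_band_labels)[band_draw]
    return df


def simulate_latents(covariates: pd.DataFrame, params: HCMParameterSet, seed: int = 0) -> pd.DataFrame:
    """Evaluate the structural recursion HR -> AW -> VAL with N(0,1) disturbances."""
    z = covariates[STRUCTURAL_COVARIATES].to_numpy(float)
    n = len(z)
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, 3))
    hr = z @ params.gamma_HR + eta[:, 0]
    aw = z @ params.gamma_AW + params.lam_hr_aw * hr + eta[:, 1]
    val = z @ params.gamma_VAL + params.lam_hr_val * hr + params.lam_aw_val * aw + eta[:, 2]
    return pd.DataFrame({"respondent": covariates["respondent"].to_numpy(),
                         "HR": hr, "AW": aw, "VAL": val})


def indicator_category_probs(lv: np.ndarray, zeta: float, tau: np.ndarray) -> np.ndarray:
    """Ordered-logit category probabilities P(I = k | LV), k = 1..5.

    P(I = k) = logistic(tau_k - zeta*LV) - logistic(tau_{k-1} - zeta*LV) with
    tau_0 = -inf, tau_5 = +inf.
    """
    tau = np.asarray(tau, float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lv = np.atleast_1d(np.asarray(lv, float))
    cum = expit(tau[None, :] - zeta * lv[:, None])          # (n, 4)
    cum = np.concatenate([np.zeros((len(lv), 1)), cum, np.ones((len(lv), 1))], axis=1)
    return np.diff(cum, axis=1)


def simulate_indicators(latents: pd.DataFrame, params: HCMParameterSet, seed: int = 0) -> pd.DataFrame:
    """Sample the 11 five-point Likert indicators from the ordered-logit model."""
    rng = np.random.default_rng(seed)
    n = len(latents)
    out = {"respondent": latents["respondent"].to_numpy()}
    for i, (name, construct) in enumerate(INDICATORS):
        probs = indicator_category_probs(
            latents[construct].to_numpy(), params.zeta[i], params.tau[i]
        )
        u = rng.random(n)
        out[name] = 1 + (u[:, None] > np.cumsum(probs, axis=1)[:, :4]).sum(axis=1)
    return pd.DataFrame(out)


def _interaction_matrix(latents: pd.DataFrame, covariates: pd.DataFrame) -> np.ndarray:
    """(n, 9) matrix of interaction variables [HR, AW, VAL, z...]."""
    return np.column_stack(
        [latents[c].to_numpy(float) for c in CONSTRUCTS]
        + [covariates[c].to_numpy(float) for c in STRUCTURAL_COVARIATES]
    )


def assign_blocks(covariates: pd.DataFrame, n_blocks: int, seed: int = 0) -> pd.DataFrame:
    """Balanced random assignment of respondents to design blocks."""
    rng = np.random.default_rng(seed)
    n = len(covariates)
    blocks = np.tile(np.arange(1, n_blocks + 1), n // n_blocks + 1)[:n]
    rng.shuffle(blocks)
    out = covariates.copy()
    out["block"] = blocks
    return out


def simulate_choices(
    covariates: pd.DataFrame,
    latents: pd.DataFrame,
    design: ChoiceDesign,
    params: HCMParameterSet,
    seed: int = 0,
    inattentive_fraction: float = 0.0,
) -> pd.DataFrame:
    """Panel MNL choices over each respondent's block tasks plus the QC task.

    Random coefficients are drawn once per respondent.  Exactly
    round(inattentive_fraction * n) respondents pick the dominated QC
    alternative; all others pick the dominant one.
    """
    if "block" not in covariates.columns:
        raise ValueError("respondents need a block assignment (see assign_blocks)")
    attrs = design.attrs
    cols = coded_columns(attrs)
    rng = np.random.default_rng(seed)
    n = len(covariates)

    sigma_vec = np.array([params.sigma.get(c, 0.0) for c in cols])
    b_vec = np.array([params.b[c] for c in cols])
    theta_mat = np.zeros((len(cols), len(INTERACTION_VARIABLES)))
    for (slot, var), v in params.theta.items():
        theta_mat[cols.index(slot), INTERACTION_VARIABLES.index(var)] = v
    M = _interaction_matrix(latents, covariates)            # (n, 9)
    lv = latents[CONSTRUCTS].to_numpy(float)
    phi_vec = np.array([params.phi[c] for c in CONSTRUCTS])

    xi = rng.standard_normal((n, len(cols)))
    beta = b_vec + sigma_vec * xi + M @ theta_mat.T          # (n, K)
    v_opt = params.delta + lv @ phi_vec                      # (n,)

    n_inatt = int(round(inattentive_fraction * n))
    inattentive = np.zeros(n, bool)
    inattentive[rng.choice(n, size=n_inatt, replace=False)] = True

    coded = {
        s.set_id: np.vstack([code_profile(p, attrs) for p in s.alternatives])
        for s in design.choice_sets
    }
    qc = design.qc_sets[0] if design.qc_sets else None
    if qc is not None:
        a0, a1 = qc.alternatives
        qc_dominant = 0 if is_dominated(a1, a0, attrs) else 1

    rows = []
    resp_ids = covariates["respondent"].to_numpy()
    block_ids = covariates["block"].to_numpy()
    for idx in range(n):
        rid = resp_ids[idx]
        tasks = sorted(design.block_of(int(block_ids[idx])), key=lambda s: s.set_id)
        for s in tasks:
            X = coded[s.set_id]
            v = np.append(X @ beta[idx], v_opt[idx])
            chosen = int(np.argmax(v + rng.gumbel(size=3)))
            for j in range(3):
                row = {"respondent": rid, "set_id": s.set_id, "alt_id": j + 1,
                       "is_optout": int(j == 2), "is_qc": 0,
                       "chosen": int(j == chosen)}
                for k, c in enumerate(cols):
                    row[c] = X[j, k] if j < 2 else 0.0
                rows.append(row)
        if qc is not None:
            X = coded[qc.set_id]
            chosen = (1 - qc_dominant) if inattentive[idx] else qc_dominant
            for j in range(3):
                row = {"respondent": rid, "set_id": qc.set_id, "alt_id": j + 1,
                       "is_optout": int(j == 2), "is_qc": 1,
                       "chosen": int(j == chosen)}
                for k, c in enumerate(cols):
                    row[c] = X[j, k] if j < 2 else 0.0
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SurveyDataset:
    """Respondent covariates, Likert indicators, long choice records, design."""

    respondents: pd.DataFrame
    indicators: pd.DataFrame
    choices: pd.DataFrame
    design: ChoiceDesign
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        tasks = self.choices.groupby("respondent")["set_id"].nunique()
        n_exp = len(self.design.experimental_sets) // max(len(self.design.blocks), 1)
        want = n_exp + len(self.design.qc_sets)
        if not (tasks == want).all():
            raise ValueError(f"every respondent must have {want} tasks")
        per_task = self.choices.groupby(["respondent", "set_id"])["chosen"].sum()
        if not (per_task == 1).all():
            raise ValueError("exactly one chosen alternative per task")


def simulate_survey(
    design: ChoiceDesign,
    params: HCMParameterSet | None = None,
    n: int = 1203,
    inattentive_fraction: float = 67 / 1203,
    seed: int = 0,
    proportions: dict | None = None,
) -> SurveyDataset:
    """End-to-end synthetic survey: covariates, latents, indicators, choices."""
    if params is None:
        params = default_true_params()
    ss = np.random.SeedSequence(seed)
    s_cov, s_lat, s_ind, s_cho, s_blk = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    cov = sample_covariates(n, proportions, seed=s_cov)
    cov = assign_blocks(cov, n_blocks=max(len(design.blocks), 1), seed=s_blk)
    lat = simulate_latents(cov, params, seed=s_lat)
    ind = simulate_indicators(lat, params, seed=s_ind)
    cho = simulate_choices(cov, lat, design, params, seed=s_cho,
                           inattentive_fraction=inattentive_fraction)
    meta = {"seed": seed, "n": n, "inattentive_fraction": inattentive_fraction,
            "parameter_provenance": dict(params.provenance)}
    ds = SurveyDataset(respondents=cov, indicators=ind, choices=cho, design=design, meta=meta)
    ds.validate()
    return ds


def dataset_checksum(ds: SurveyDataset) -> str:
    """SHA-256 over the three CSV-rendered tables (determinism checks)."""
    h = hashlib.sha256()
    for df in (ds.respondents, ds.indicators, ds.choices):
        h.update(df.to_csv(index=False).encode())
    return h.hexdigest()
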
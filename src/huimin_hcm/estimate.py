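"""Joint simulated-maximum-likelihood estimation of the hybrid choice model.

The model integrates three components, estimated simultaneously:

* structural:  HR = g_HR.z + eta1;  AW = g_AW.z + l1*HR + eta2;
               VAL = g_VAL.z + l2*HR + l3*AW + eta3,  eta ~ N(0,1)
* measurement: 11 five-point Likert indicators, ordered logit with loading
               zeta_i and strictly increasing thresholds tau_i
* choice:      panel mixed logit over 6 tasks of 3 alternatives (two
               insurance packages + opt-out); insurance utility
               V = sum_k (b_k + |sigma_k| xi_k + theta_k.[LV,z]) x_k,
               opt-out utility delta + phi.LV; iid Gumbel errors.

The per-respondent likelihood is simulated with scrambled Halton draws over
the 3 latent disturbances and the random coefficients (one joint draw block
per respondent, shared across that respondent's tasks), and maximized by
quasi-Newton with analytic gradients.  Robust (sandwich) standard errors use
the outer product of per-respondent scores.

The opt-out enters the design matrix as an extra dummy column, so the ASC
and the latent opt-out shifts are ordinary coefficients/interactions of a
single J-generic logit kernel; the stand-alone mixed logit and plain MNL are
the same kernel with components switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm, qmc

from .design import AttributeDictionary, coded_columns
from .simulate import (
    CONSTRUCTS,
    INDICATOR_NAMES,
    INDICATORS,
    INTERACTION_VARIABLES,
    RANDOM_SLOTS,
    STRUCTURAL_COVARIATES,
    HCMParameterSet,
    SurveyDataset,
)

OPTOUT_COL = "optout"
_TAU_DEFAULT = np.array([-2.0, -0.5, 0.5, 2.0])

__all__ = [
    "DrawConfig",
    "ModelSpec",
    "EstimationResult",
    "halton_sequence",
    "make_draws",
    "mnl_probabilities",
    "conditional_utility",
    "person_likelihood",
    "simulated_loglik",
    "enumerate_interactions",
    "fit_mnl",
    "fit_mixed_logit",
    "fit_hcm",
    "robust_se",
    "wtp",
    "significance_stars",
]


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrawConfig:
    """Simulation draws: scheme, count per respondent, seed."""

    scheme: str = "scrambled-halton"
    n_draws: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.scheme not in ("scrambled-halton", "mlhs", "pseudo-random"):
            raise ValueError(f"unknown draw scheme {self.scheme!r}")


def halton_sequence(
    n_individuals: int,
    dimensions: int,
    n_draws: int,
    seed: int = 0,
    scramble: bool = True,
) -> np.ndarray:
    """Standard-normal (scrambled) Halton draws, shape (n_individuals, n_draws, dimensions).

    Consecutive blocks of the sequence go to consecutive individuals.  The
    leading zero point of the unscrambled sequence is skipped.
    """
    if dimensions > 20:
        raise ValueError("Halton draws limited to 20 dimensions")
    engine = qmc.Halton(d=dimensions, scramble=scramble, seed=seed)
    engine.fast_forward(1)
    u = engine.random(n_individuals * n_draws)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return norm.ppf(u).reshape(n_individuals, n_draws, dimensions)


def _mlhs(n_individuals, dimensions, n_draws, seed):
    rng = np.random.default_rng(seed)
    out = np.empty((n_individuals, n_draws, dimensions))
    for i in range(n_individuals):
        for d in range(dimensions):
            perm = rng.permutation(n_draws)
            out[i, :, d] = (perm + rng.random(n_draws)) / n_draws
    return norm.ppf(np.clip(out, 1e-12, 1 - 1e-12))


def make_draws(n_individuals: int, n_latent: int, n_random: int, config: DrawConfig):
    """eta (n,R,n_latent) and xi (n,R,n_random) blocks from one joint sequence."""
    d = n_latent + n_random
    if d == 0:
        R = config.n_draws
        zero = np.zeros((n_individuals, 1, 0))
        return {"eta": zero, "xi": zero, "R": 1}
    if config.scheme == "scrambled-halton":
        draws = halton_sequence(n_individuals, d, config.n_draws, config.seed)
    elif config.scheme == "mlhs":
        draws = _mlhs(n_individuals, d, config.n_draws, config.seed)
    else:
        draws = np.random.default_rng(config.seed).standard_normal(
            (n_individuals, config.n_draws, d)
        )
    return {"eta": draws[:, :, :n_latent], "xi": draws[:, :, n_latent:], "R": config.n_draws}


# ---------------------------------------------------------------------------
# Model specification and parameter packing
# ---------------------------------------------------------------------------

def enumerate_interactions(
    random_slots=tuple(RANDOM_SLOTS), variables=tuple(INTERACTION_VARIABLES)
):
    """All candidate mean-shift interactions: random attribute levels x variables."""
    return [(s, v) for s in random_slots for v in variables]


@dataclass(frozen=True)
class ModelSpec:
    """Which components are active and which coefficients are random/interacted."""

    coded_cols: tuple
    latent: bool = True
    random_slots: tuple = tuple(RANDOM_SLOTS)
    interactions: tuple = ()

    def __post_init__(self):
        for s in self.random_slots:
            if s not in self.coded_cols:
                raise ValueError(f"random slot {s!r} not a coded column")
        for s, v in self.interactions:
            if s not in self.coded_cols:
                raise ValueError(f"interaction slot {s!r} not a coded column")
            if v not in INTERACTION_VARIABLES:
                raise ValueError(f"unknown interaction variable {v!r}")
            if not self.latent and v in CONSTRUCTS:
                raise ValueError("latent interactions require latent=True")

    @classmethod
    def hcm(cls, attrs: AttributeDictionary, interactions=None) -> "ModelSpec":
        if interactions is None:
            interactions = enumerate_interactions()
        return cls(coded_cols=tuple(coded_columns(attrs)), latent=True,
                   random_slots=tuple(RANDOM_SLOTS), interactions=tuple(interactions))

    @classmethod
    def mixed_logit(cls, attrs: AttributeDictionary, random_slots=None) -> "ModelSpec":
        cols = tuple(coded_columns(attrs))
        return cls(coded_cols=cols, latent=False,
                   random_slots=cols if random_slots is None else tuple(random_slots),
                   interactions=())

    @classmethod
    def mnl(cls, attrs: AttributeDictionary) -> "ModelSpec":
        return cls(coded_cols=tuple(coded_columns(attrs)), latent=False,
                   random_slots=(), interactions=())


class _Packer:
    """Flat parameter vector <-> named blocks for one ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.cols = list(spec.coded_cols) + [OPTOUT_COL]
        self.Kc = len(self.cols)
        self.S = len(spec.random_slots)
        self.nI = len(spec.interactions)
        self.names = [f"b:{c}" for c in spec.coded_cols] + ["optout_asc"]
        self.names += [f"sd:{s}" for s in spec.random_slots]
        if spec.latent:
            self.names += [f"phi:{c}" for c in CONSTRUCTS]
        self.names += [f"theta:{s}*{v}" for s, v in spec.interactions]
        if spec.latent:
            for g in CONSTRUCTS:
                self.names += [f"gamma_{g}:{z}" for z in STRUCTURAL_COVARIATES]
            self.names += ["lam_hr_aw", "lam_hr_val", "lam_aw_val"]
            self.names += [f"zeta:{i}" for i in INDICATOR_NAMES]
            for i in INDICATOR_NAMES:
                self.names += [f"tau_{i}:1", f"tau_{i}:logd2", f"tau_{i}:logd3", f"tau_{i}:logd4"]
        self.n_params = len(self.names)
        self.random_idx = np.array(
            [self.cols.index(s) for s in spec.random_slots], dtype=int
        )

    def theta_matrix(self, phi, theta):
        """Scatter phi (opt-out x latents) and theta into a (Kc, 9) matrix."""
        T = np.zeros((self.Kc, len(INTERACTION_VARIABLES)))
        for j, (s, v) in enumerate(self.spec.interactions):
            T[self.cols.index(s), INTERACTION_VARIABLES.index(v)] = theta[j]
        if self.spec.latent:
            for c, construct in enumerate(CONSTRUCTS):
                T[self.Kc - 1, c] = phi[c]
        return T

    def unpack(self, p):
        p = np.asarray(p, float)
        i = 0
        out = {}
        out["beta_fixed"] = p[i:i + self.Kc]; i += self.Kc
        out["sigma"] = p[i:i + self.S]; i += self.S
        if self.spec.latent:
            out["phi"] = p[i:i + 3]; i += 3
        else:
            out["phi"] = np.zeros(3)
        out["theta"] = p[i:i + self.nI]; i += self.nI
        if self.spec.latent:
            out["gamma"] = p[i:i + 18].reshape(3, 6); i += 18
            out["lam"] = p[i:i + 3]; i += 3
            out["zeta"] = p[i:i + 11]; i += 11
            out["tau_raw"] = p[i:i + 44].reshape(11, 4); i += 44
        assert i == len(p)
        return out

    def pack(self, **blocks):
        parts = [blocks["beta_fixed"], blocks["sigma"]]
        if self.spec.latent:
            parts.append(blocks["phi"])
        parts.append(blocks["theta"])
        if self.spec.latent:
            parts += [blocks["gamma"].ravel(), blocks["lam"],
                      blocks["zeta"], blocks["tau_raw"].ravel()]
        return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def _tau_from_raw(raw):
    """(11,4) raw (t1, log-increments) -> strictly increasing thresholds."""
    tau = np.empty_like(raw)
    tau[:, 0] = raw[:, 0]
    tau[:, 1:] = raw[:, 0][:, None] + np.cumsum(np.exp(raw[:, 1:]), axis=1)
    return tau


def _raw_from_tau(tau):
    raw = np.empty_like(tau)
    raw[:, 0] = tau[:, 0]
    raw[:, 1:] = np.log(np.diff(tau, axis=1))
    return raw


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

@dataclass
class ChoiceArrays:
    """Rectangular arrays for the likelihood kernel."""

    X: np.ndarray          # (n, T, J, Kc) coded attributes + opt-out dummy
    y: np.ndarray          # (n, T) chosen alternative index
    z: np.ndarray          # (n, 6) structural covariates
    I: np.ndarray          # (n, 11) indicators, NaN = missing
    respondents: np.ndarray
    cols: list
    _X2: np.ndarray = None   # (n, T*J, Kc) cache for batched matmul
    _X2T: np.ndarray = None  # (n, Kc, T*J)

    def flat(self):
        if self._X2 is None:
            n, T, J, Kc = self.X.shape
            self._X2 = np.ascontiguousarray(self.X.reshape(n, T * J, Kc))
            self._X2T = np.ascontiguousarray(self._X2.transpose(0, 2, 1))
        return self._X2, self._X2T

    def indicator_index(self):
        """Per-indicator category bookkeeping for the ordered-logit block."""
        if not hasattr(self, "_meas"):
            cat = self.I
            mask = ~np.isnan(cat)
            cat_i = np.where(mask, cat, 3).astype(int)            # (n,11)
            self._meas = {
                "mask": mask,
                "maskf": mask.astype(float),
                "cat": cat_i,
                "hi_idx": np.minimum(cat_i, 4) - 1,               # tau index of upper cut
                "lo_idx": np.maximum(cat_i, 2) - 2,               # tau index of lower cut
                "top": cat_i == 5,
                "bot": cat_i == 1,
            }
        return self._meas


def prepare_arrays(dataset: SurveyDataset, attrs: AttributeDictionary | None = None) -> ChoiceArrays:
    """Experimental (non-QC) tasks as rectangular arrays, respondent-sorted."""
    attrs = attrs or dataset.design.attrs
    cols = coded_columns(attrs)
    cho = dataset.choices
    exp = cho[cho["is_qc"] == 0].sort_values(["respondent", "set_id", "alt_id"])
    resp_ids = np.sort(exp["respondent"].unique())
    n = len(resp_ids)
    counts = exp.groupby("respondent")["set_id"].nunique()
    T = int(counts.iloc[0])
    if not (counts == T).all():
        raise ValueError("unbalanced panel: respondents differ in task counts")
    J = int(len(exp) // (n * T))
    Kc = len(cols) + 1
    Xmat = exp[cols].to_numpy(float)
    X = np.concatenate(
        [Xmat, exp["is_optout"].to_numpy(float)[:, None]], axis=1
    ).reshape(n, T, J, Kc)
    chosen = exp["chosen"].to_numpy().reshape(n, T, J)
    y = chosen.argmax(axis=2)
    resp = dataset.respondents.set_index("respondent").loc[resp_ids]
    z = resp[STRUCTURAL_COVARIATES].to_numpy(float)
    ind = dataset.indicators.set_index("respondent").reindex(resp_ids)
    I = ind[INDICATOR_NAMES].to_numpy(float)
    return ChoiceArrays(X=X, y=y, z=z, I=I, respondents=resp_ids, cols=cols)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def mnl_probabilities(utilities) -> np.ndarray:
    """Softmax choice probabilities over the alternatives of one task."""
    u = np.asarray(utilities, float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    e = np.exp(u - u.max())
    return e / e.sum()


def conditional_utility(
    profile: dict | None,
    covariates: dict,
    latents: dict,
    xi: dict,
    params: HCMParameterSet,
    attrs: AttributeDictionary,
) -> float:
    """Utility of one alternative conditional on one joint draw.

    ``profile=None`` denotes the opt-out: V = delta + phi.LV.  Insurance
    alternatives get V = sum_k (b_k + |sigma_k| xi_k + theta_k.[LV,z]) x_k.
    """
    if profile is None:
        return params.delta + sum(params.phi[c] * latents[c] for c in CONSTRUCTS)
    from .design import code_profile

    x = code_profile(profile, attrs)
    cols = coded_columns(attrs)
    v = 0.0
    for k, c in enumerate(cols):
        beta = params.b[c] + abs(params.sigma.get(c, 0.0)) * xi.get(c, 0.0)
        for (slot, var), coef in params.theta.items():
            if slot == c:
                val = latents[var] if var in CONSTRUCTS else covariates[var]
                beta += coef * val
        v += beta * x[k]
    return float(v)


def _ordered_logit_logprob(category, zeta, lv, tau):
    """log P(I = category | LV) for one indicator (scalar reference code)."""
    u = zeta * lv
    hi = tau[category - 1] - u if category <= 4 else np.inf
    lo = tau[category - 2] - u if category >= 2 else -np.inf
    return float(np.log(expit(hi) - expit(lo)))


def person_likelihood(
    records: pd.DataFrame,
    indicators: dict,
    covariates: dict,
    draw: dict,
    params: HCMParameterSet,
    attrs: AttributeDictionary,
) -> float:
    """Joint likelihood of one respondent conditional on one joint draw.

    Product over experimental tasks of the chosen-alternative MNL probability
    times the product over non-missing indicators of the ordered-logit
    category probability.  ``draw`` holds 'eta' (3 structural disturbances)
    and 'xi' (one N(0,1) per random slot).  Readable reference
    implementation; the vectorized kernel is checked against it.
    """
    eta = draw["eta"]
    z = np.array([covariates[c] for c in STRUCTURAL_COVARIATES], float)
    hr = float(params.gamma_HR @ z) + eta[0]
    aw = float(params.gamma_AW @ z) + params.lam_hr_aw * hr + eta[1]
    val = (float(params.gamma_VAL @ z) + params.lam_hr_val * hr
           + params.lam_aw_val * aw + eta[2])
    lv = {"HR": hr, "AW": aw, "VAL": val}
    xi = dict(draw.get("xi", {}))   # coded column -> N(0,1) taste draw

    like = 1.0
    exp_rec = records[records["is_qc"] == 0]
    for _, task in exp_rec.groupby("set_id"):
        task = task.sort_values("alt_id")
        utilities = []
        for _, row in task.iterrows():
            if row["is_optout"]:
                utilities.append(params.delta + sum(params.phi[c] * lv[c] for c in CONSTRUCTS))
            else:
                v = 0.0
                for c in coded_columns(attrs):
                    beta = params.b[c] + abs(params.sigma.get(c, 0.0)) * xi.get(c, 0.0)
                    for (slot, var), coef in params.theta.items():
                        if slot == c:
                            beta += coef * (lv[var] if var in CONSTRUCTS else covariates[var])
                    v += beta * row[c]
                utilities.append(v)
        p = mnl_probabilities(utilities)
        chosen = int(np.argmax(task["chosen"].to_numpy()))
        like *= p[chosen]
    for i, (name, construct) in enumerate(INDICATORS):
        cat = indicators.get(name, np.nan)
        if np.isnan(cat):
            continue
        like *= np.exp(_ordered_logit_logprob(int(cat), params.zeta[i], lv[construct],
                                              params.tau[i]))
    return float(like)


# ---------------------------------------------------------------------------
# Vectorized simulated likelihood and analytic gradient
# ---------------------------------------------------------------------------

def _loglik_core(pvec, arrays: ChoiceArrays, packer: _Packer, draws,
                 want_grad=True, want_scores=False):
    """Simulated log-likelihood (sum over respondents), gradient, scores.

    Returns (loglik, grad, scores) on the sum scale; grad/scores are None
    when not requested.
    """
    spec = packer.spec
    blocks = packer.unpack(pvec)
    X, y, z, I = arrays.X, arrays.y, arrays.z, arrays.I
    n, T, J, Kc = X.shape
    eta, xi = draws["eta"], draws["xi"]
    R = eta.shape[1] if spec.latent else (xi.shape[1] if packer.S else 1)
    if xi.shape[2] != packer.S and packer.S:
        raise ValueError("draw dimensions inconsistent with random slots")

    beta_fixed = blocks["beta_fixed"]
    sigma = blocks["sigma"]
    theta_mat = packer.theta_matrix(blocks["phi"], blocks["theta"])

    # latent constructs per draw
    if spec.latent:
        g = blocks["gamma"]
        l1, l2, l3 = blocks["lam"]
        hr = (z @ g[0])[:, None] + eta[:, :, 0]
        aw = (z @ g[1])[:, None] + l1 * hr + eta[:, :, 1]
        val = (z @ g[2])[:, None] + l2 * hr + l3 * aw + eta[:, :, 2]
        LV = np.stack([hr, aw, val], axis=2)                     # (n,R,3)
        M = np.concatenate([LV, np.broadcast_to(z[:, None, :], (n, R, 6))], axis=2)
    else:
        LV = np.zeros((n, R, 3))
        M = np.concatenate([LV, np.broadcast_to(z[:, None, :], (n, R, 6))], axis=2)

    # per-draw coefficients on the coded columns
    beta = np.broadcast_to(beta_fixed, (n, R, Kc)).copy()
    if packer.S:
        beta[:, :, packer.random_idx] += np.abs(sigma) * xi
    if theta_mat.any():
        beta += M @ theta_mat.T

    X2, X2T = arrays.flat()
    V = np.matmul(beta, X2T).reshape(n, R, T, J)                  # batched GEMM
    Vmax = V[:, :, :, 0].copy()                                   # small-J max via slices
    for j in range(1, J):
        np.maximum(Vmax, V[:, :, :, j], out=Vmax)
    V -= Vmax[:, :, :, None]
    idx_n = np.arange(n)[:, None, None]
    idx_r = np.arange(R)[None, :, None]
    idx_t = np.arange(T)[None, None, :]
    y_idx = y[:, None, :]
    Vc = V[idx_n, idx_r, idx_t, y_idx]                            # (n,R,T) chosen
    np.exp(V, out=V)                                              # V is now exp(V - max)
    denom = V[:, :, :, 0].copy()
    for j in range(1, J):
        denom += V[:, :, :, j]
    Vc -= np.log(denom)
    CL = Vc.sum(axis=2)                                           # (n,R)

    # measurement component, vectorized over the 11 indicators
    ML = np.zeros((n, R))
    meas = None
    if spec.latent:
        zeta = blocks["zeta"]
        tau = _tau_from_raw(blocks["tau_raw"])
        cidx = np.array([CONSTRUCTS.index(c) for _, c in INDICATORS])
        mi = arrays.indicator_index()
        nI11 = len(INDICATORS)
        U = LV[:, :, cidx] * zeta                                 # (n,R,11)
        rows = np.arange(nI11)
        hi_t = tau[rows, mi["hi_idx"]]                            # (n,11)
        lo_t = tau[rows, mi["lo_idx"]]
        Phi_hi = expit(hi_t[:, None, :] - U)
        Phi_hi[np.broadcast_to(mi["top"][:, None, :], Phi_hi.shape)] = 1.0
        Phi_lo = expit(lo_t[:, None, :] - U)
        Phi_lo[np.broadcast_to(mi["bot"][:, None, :], Phi_lo.shape)] = 0.0
        Pi = Phi_hi - Phi_lo
        np.clip(Pi, 1e-300, None, out=Pi)                         # (n,R,11)
        logPi = np.log(Pi)
        logPi *= mi["maskf"][:, None, :]
        ML = logPi.sum(axis=2)
        meas = (mi, Pi, Phi_hi, Phi_lo, cidx)

    logf = CL + ML
    lse = logsumexp(logf, axis=1)
    loglik = float(np.sum(lse - np.log(R)))

    if not (want_grad or want_scores):
        return loglik, None, None

    w = np.exp(logf - lse[:, None])                               # (n,R), sums to 1 over r

    # V currently holds exp(V - max); turn it into w * (Y - P) in place
    V /= denom[:, :, :, None]                                     # now P
    np.negative(V, out=V)
    V[idx_n, idx_r, idx_t, y_idx] += 1.0                          # now E = Y - P
    V *= w[:, :, None, None]                                      # now WE
    A = np.matmul(V.reshape(n, R, T * J), X2)                     # (n,R,Kc)

    per = {}
    per["beta_fixed"] = A.sum(axis=1)                             # (n,Kc)
    if packer.S:
        per["sigma"] = np.sign(sigma) * np.einsum(
            "nrs,nrs->ns", A[:, :, packer.random_idx], xi
        )
    else:
        per["sigma"] = np.zeros((n, 0))
    if packer.nI:
        th_scores = np.matmul(A.transpose(0, 2, 1), M)            # (n,Kc,9)
        per["theta"] = np.stack(
            [th_scores[:, packer.cols.index(s), INTERACTION_VARIABLES.index(v)]
             for s, v in spec.interactions], axis=1
        )
    else:
        per["theta"] = np.zeros((n, 0))

    if spec.latent:
        per["phi"] = np.einsum("nr,nrc->nc", A[:, :, Kc - 1], LV)

        # score wrt each latent construct, weighted by w
        S_lv = A @ theta_mat[:, :3]                               # (n,R,3)
        mi, Pi, Phi_hi, Phi_lo, cidx = meas
        wmask = w[:, :, None] * mi["maskf"][:, None, :]           # (n,R,11)
        # dhi = Lam'(hi)/P, dlo = Lam'(lo)/P, both premultiplied by w and mask
        Phi_hi -= Phi_hi * Phi_hi                                 # now Lam'(hi)
        Phi_hi *= wmask
        Phi_hi /= Pi                                              # now w*dhi
        Phi_lo -= Phi_lo * Phi_lo
        Phi_lo *= wmask
        Phi_lo /= Pi                                              # now w*dlo
        wd = Phi_lo - Phi_hi                                      # w * dlogP/du
        g_zeta = np.einsum("nri,nri->ni", wd, LV[:, :, cidx])     # (n,11)
        # accumulate construct scores: sum_i (wd_i * zeta_i) into construct c(i)
        C = np.zeros((len(INDICATORS), 3))
        C[np.arange(len(INDICATORS)), cidx] = zeta
        S_lv += wd @ C
        # thresholds: upper cut at hi_idx (cat<=4), lower cut at lo_idx (cat>=2)
        whi = Phi_hi.sum(axis=1)                                  # (n,11)
        wlo = Phi_lo.sum(axis=1)
        whi[mi["top"]] = 0.0
        wlo[mi["bot"]] = 0.0
        g_tau = np.zeros((n, 11, 4))
        for m in range(4):
            g_tau[:, :, m] = np.where(mi["hi_idx"] == m, whi, 0.0) \
                - np.where(mi["lo_idx"] == m, wlo, 0.0)

        eff_val = S_lv[:, :, 2]
        eff_aw = S_lv[:, :, 1] + l3 * eff_val
        eff_hr = S_lv[:, :, 0] + l1 * eff_aw + l2 * eff_val
        per["gamma"] = np.concatenate(
            [eff_hr.sum(axis=1)[:, None] * z,
             eff_aw.sum(axis=1)[:, None] * z,
             eff_val.sum(axis=1)[:, None] * z], axis=1
        )                                                         # (n,18)
        per["lam"] = np.stack(
            [(eff_aw * hr).sum(axis=1), (eff_val * hr).sum(axis=1),
             (eff_val * aw).sum(axis=1)], axis=1
        )
        per["zeta"] = g_zeta
        # chain thresholds through (t1, log-increments)
        raw = blocks["tau_raw"]
        g_raw = np.empty((n, 11, 4))
        g_raw[:, :, 0] = g_tau.sum(axis=2)
        for j in range(1, 4):
            g_raw[:, :, j] = np.exp(raw[:, j])[None, :] * g_tau[:, :, j:].sum(axis=2)
        per["tau_raw"] = g_raw.reshape(n, 44)

    order = ["beta_fixed", "sigma"] + (["phi"] if spec.latent else []) + ["theta"]
    if spec.latent:
        order += ["gamma", "lam", "zeta", "tau_raw"]
    scores = np.concatenate([per[k] for k in order], axis=1)      # (n, P)
    grad = scores.sum(axis=0)
    return loglik, grad, (scores if want_scores else None)


def simulated_loglik(
    dataset: SurveyDataset,
    params: HCMParameterSet,
    draws: DrawConfig,
    spec: ModelSpec | None = None,
) -> float:
    """Simulated log-likelihood sum_n ln (1/R sum_r f_nr) at given parameters."""
    attrs = dataset.design.attrs
    if spec is None:
        spec = ModelSpec.hcm(attrs, interactions=sorted(params.theta.keys()))
    arrays = prepare_arrays(dataset, attrs)
    packer = _Packer(spec)
    pvec = _pvec_from_params(params, packer)
    d = make_draws(len(arrays.respondents), 3 if spec.latent else 0, packer.S, draws)
    ll, _, _ = _loglik_core(pvec, arrays, packer, d, want_grad=False)
    return ll


def _pvec_from_params(params: HCMParameterSet, packer: _Packer) -> np.ndarray:
    spec = packer.spec
    beta_fixed = np.array([params.b[c] for c in spec.coded_cols] + [params.delta])
    sigma = np.array([params.sigma.get(s, 0.0) for s in spec.random_slots])
    theta = np.array([params.theta.get(pair, 0.0) for pair in spec.interactions])
    blocks = dict(beta_fixed=beta_fixed, sigma=sigma, theta=theta)
    if spec.latent:
        blocks["phi"] = np.array([params.phi[c] for c in CONSTRUCTS])
        blocks["gamma"] = np.vstack([params.gamma_HR, params.gamma_AW, params.gamma_VAL])
        blocks["lam"] = np.array([params.lam_hr_aw, params.lam_hr_val, params.lam_aw_val])
        blocks["zeta"] = params.zeta
        blocks["tau_raw"] = _raw_from_tau(params.tau)
    return packer.pack(**blocks)


def _params_from_pvec(pvec, packer: _Packer) -> HCMParameterSet:
    spec = packer.spec
    blocks = packer.unpack(pvec)
    b = dict(zip(spec.coded_cols, blocks["beta_fixed"][:-1]))
    sigma = {s: abs(v) for s, v in zip(spec.random_slots, blocks["sigma"])}
    theta = dict(zip(spec.interactions, blocks["theta"]))
    if spec.latent:
        gamma = blocks["gamma"]
        tau = _tau_from_raw(blocks["tau_raw"])
        return HCMParameterSet(
            gamma_HR=gamma[0], gamma_AW=gamma[1], gamma_VAL=gamma[2],
            lam_hr_aw=float(blocks["lam"][0]), lam_hr_val=float(blocks["lam"][1]),
            lam_aw_val=float(blocks["lam"][2]),
            zeta=blocks["zeta"], tau=tau, b=b, sigma=sigma, theta=theta,
            delta=float(blocks["beta_fixed"][-1]),
            phi=dict(zip(CONSTRUCTS, blocks["phi"])),
        )
    return HCMParameterSet(
        gamma_HR=np.zeros(6), gamma_AW=np.zeros(6), gamma_VAL=np.zeros(6),
        lam_hr_aw=0.0, lam_hr_val=0.0, lam_aw_val=0.0,
        zeta=np.zeros(11), tau=np.tile(_TAU_DEFAULT, (11, 1)),
        b=b, sigma=sigma, theta=theta,
        delta=float(blocks["beta_fixed"][-1]), phi={c: 0.0 for c in CONSTRUCTS},
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    """Point estimates with classical and robust (sandwich) standard errors."""

    estimates: HCMParameterSet
    param_names: list
    pvec: np.ndarray
    robust_se: np.ndarray | None
    classical_se: np.ndarray | None
    loglik: float
    n_individuals: int
    n_tasks: int
    gradient_norm: float
    converged: bool
    draw_config: DrawConfig | None
    spec: ModelSpec
    robust_cov: np.ndarray | None = None
    classical_cov: np.ndarray | None = None
    n_iter: int = 0
    message: str = ""

    def table(self) -> pd.DataFrame:
        """Estimates with robust SEs, z, two-sided normal p-values, stars."""
        est = self.pvec.copy()
        for j, nm in enumerate(self.param_names):   # SDs are sign-invariant
            if nm.startswith("sd:"):
                est[j] = abs(est[j])
        se = self.robust_se if self.robust_se is not None else self.classical_se
        rows = {"parameter": self.param_names, "estimate": est}
        if se is not None:
            zval = est / se
            p = 2 * norm.sf(np.abs(zval))
            rows.update(robust_se=se, z=zval, p_value=p,
                        stars=[significance_stars(v) for v in p])
        return pd.DataFrame(rows)

    def get(self, name: str) -> float:
        return float(self.pvec[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        se = self.robust_se if self.robust_se is not None else self.classical_se
        return float(se[self.param_names.index(name)])


def significance_stars(p: float) -> str:
    """Stars at the 1% / 5% / 10% two-sided levels."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def _numeric_hessian(fun_grad, p, step=1e-5):
    """Forward-difference Hessian of a scalar function from its analytic gradient."""
    P = len(p)
    g0 = fun_grad(p)
    H = np.empty((P, P))
    for j in range(P):
        h = step * max(1.0, abs(p[j]))
        pj = p.copy()
        pj[j] += h
        H[:, j] = (fun_grad(pj) - g0) / h
    return 0.5 * (H + H.T)


def _starting_values(arrays, packer, draws_cfg, mnl_start=None):
    spec = packer.spec
    n = len(arrays.respondents)
    # plain MNL for the fixed coefficients
    if mnl_start is None:
        mnl_packer = _Packer(ModelSpec(coded_cols=spec.coded_cols, latent=False,
                                       random_slots=(), interactions=()))
        d0 = make_draws(n, 0, 0, DrawConfig(n_draws=1, seed=0))
        p0 = np.zeros(mnl_packer.n_params)

        def negll(p):
            ll, g, _ = _loglik_core(p, arrays, mnl_packer, d0)
            return -ll / n, -g / n

        res = optimize.minimize(negll, p0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 500})
        mnl_start = res.x
    blocks = dict(
        beta_fixed=mnl_start,
        sigma=np.full(packer.S, 0.1),
        theta=np.zeros(packer.nI),
    )
    if spec.latent:
        blocks["phi"] = np.full(3, 0.1)
        blocks["gamma"] = np.zeros((3, 6))
        blocks["lam"] = np.full(3, 0.1)
        blocks["zeta"] = np.ones(11)
        # quantile-matched thresholds from pooled empirical category frequencies
        raw = np.empty((11, 4))
        for i in range(11):
            cats = arrays.I[:, i]
            cats = cats[~np.isnan(cats)]
            if len(cats) == 0:
                raw[i] = _raw_from_tau(_TAU_DEFAULT[None, :])[0]
                continue
            cum = np.array([(cats <= k).mean() for k in (1, 2, 3, 4)])
            cum = np.clip(cum, 0.005, 0.995)
            tau_i = np.log(cum / (1 - cum))
            tau_i = np.maximum.accumulate(tau_i)
            for m in range(1, 4):                    # enforce strict increase
                if tau_i[m] <= tau_i[m - 1]:
                    tau_i[m] = tau_i[m - 1] + 0.05
            raw[i] = _raw_from_tau(tau_i[None, :])[0]
        blocks["tau_raw"] = raw
    return packer.pack(**blocks)


def _column_scales(packer: _Packer, arrays: ChoiceArrays) -> np.ndarray:
    """Per-parameter multipliers making coded-column magnitudes O(1) for the
    optimizer (premium in RMB etc. otherwise condition L-BFGS badly)."""
    col_scale = np.ones(packer.Kc)
    for k in range(packer.Kc - 1):                     # opt-out dummy stays 1
        col_scale[k] = max(1.0, float(np.abs(arrays.X[:, :, :, k]).max()) / 2.0)
    pscale = np.ones(packer.n_params)
    for j, nm in enumerate(packer.names):
        if nm.startswith("b:"):
            pscale[j] = col_scale[packer.spec.coded_cols.index(nm[2:])]
        elif nm.startswith("sd:"):
            pscale[j] = col_scale[packer.spec.coded_cols.index(nm[3:])]
        elif nm.startswith("theta:"):
            slot = nm[6:].split("*")[0]
            pscale[j] = col_scale[packer.spec.coded_cols.index(slot)]
    return pscale


def _fit(dataset, spec, draws_cfg, gtol=1e-6, maxiter=1000, compute_se=True,
         se_method="sandwich", hessian_step=1e-5, start=None):
    arrays = prepare_arrays(dataset)
    packer = _Packer(spec)
    n = len(arrays.respondents)
    d = make_draws(n, 3 if spec.latent else 0, packer.S, draws_cfg)

    if start is None:
        start = _starting_values(arrays, packer, draws_cfg)

    # optimize in a rescaled parameter space: q = p * pscale, X columns / scale
    pscale = _column_scales(packer, arrays)
    col_div = np.ones(packer.Kc)
    for j, nm in enumerate(packer.names):
        if nm.startswith("b:"):
            col_div[packer.spec.coded_cols.index(nm[2:])] = pscale[j]
    scaled = ChoiceArrays(X=arrays.X / col_div, y=arrays.y, z=arrays.z,
                          I=arrays.I, respondents=arrays.respondents, cols=arrays.cols)

    def negll_mean(q):
        ll, g, _ = _loglik_core(q, scaled, packer, d)
        return -ll / n, -g / n

    res = optimize.minimize(
        negll_mean, np.asarray(start) * pscale, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 5 * maxiter, "gtol": gtol,
                 "ftol": 1e-14, "maxcor": 25},
    )
    pvec = res.x / pscale
    ll, grad_s, scores_s = _loglik_core(res.x, scaled, packer, d, want_scores=True)
    gnorm = float(np.max(np.abs(grad_s / n)))          # scaled space, O(1) columns
    converged = gnorm <= gtol

    robust = classical = rcov = ccov = None
    if compute_se:
        D = np.diag(1.0 / pscale)                      # cov_p = D cov_q D
        B_q = scores_s.T @ scores_s
        if se_method == "bhhh":
            try:
                cov_q = np.linalg.inv(B_q)
                rcov = ccov = D @ cov_q @ D
                robust = classical = np.sqrt(np.clip(np.diag(rcov), 0, None))
            except np.linalg.LinAlgError:
                pass
        else:
            def grad_sum(q):
                _, g, _ = _loglik_core(q, scaled, packer, d)
                return g

            H_q = _numeric_hessian(grad_sum, res.x, step=hessian_step)
            try:
                Hinv = np.linalg.inv(-H_q)
                ccov = D @ Hinv @ D
                rcov = D @ (Hinv @ B_q @ Hinv) @ D
                classical = np.sqrt(np.clip(np.diag(ccov), 0, None))
                robust = np.sqrt(np.clip(np.diag(rcov), 0, None))
            except np.linalg.LinAlgError:
                pass  # singular Hessian: SEs flagged unavailable (None)

    return EstimationResult(
        estimates=_params_from_pvec(pvec, packer),
        param_names=list(packer.names),
        pvec=pvec,
        robust_se=robust, classical_se=classical,
        robust_cov=rcov, classical_cov=ccov,
        loglik=ll, n_individuals=n, n_tasks=n * arrays.y.shape[1],
        gradient_norm=gnorm, converged=converged,
        draw_config=draws_cfg, spec=spec,
        n_iter=int(res.nit), message=str(res.message),
    )


def fit_mnl(dataset: SurveyDataset, compute_se=True) -> EstimationResult:
    """Plain conditional (multinomial) logit: no random taste, no latents."""
    spec = ModelSpec.mnl(dataset.design.attrs)
    return _fit(dataset, spec, DrawConfig(n_draws=1, seed=0), compute_se=compute_se)


def fit_mixed_logit(
    dataset: SurveyDataset,
    draws: DrawConfig = DrawConfig(),
    random_slots=None,
    gtol: float = 1e-6,
    maxiter: int = 1000,
    compute_se: bool = True,
    se_method: str = "sandwich",
) -> EstimationResult:
    """Main-effects panel mixed logit (no latent component)."""
    spec = ModelSpec.mixed_logit(dataset.design.attrs, random_slots=random_slots)
    return _fit(dataset, spec, draws, gtol=gtol, maxiter=maxiter,
                compute_se=compute_se, se_method=se_method)


def fit_hcm(
    dataset: SurveyDataset,
    interactions=None,
    draws: DrawConfig = DrawConfig(),
    gtol: float = 1e-6,
    maxiter: int = 1000,
    compute_se: bool = True,
    se_method: str = "sandwich",
    start: np.ndarray | None = None,
) -> EstimationResult:
    """Joint simulated-ML fit of the full hybrid choice model.

    ``interactions`` is the list of (attribute slot, variable) mean-shift
    terms; default is the full 63-term candidate set (7 random attribute
    levels x 9 variables).
    """
    spec = ModelSpec.hcm(dataset.design.attrs, interactions=interactions)
    return _fit(dataset, spec, draws, gtol=gtol, maxiter=maxiter,
                compute_se=compute_se, se_method=se_method, start=start)


def robust_se(result: EstimationResult, dataset: SurveyDataset,
              hessian_step: float = 1e-5) -> np.ndarray:
    """Sandwich H^-1 B H^-1 standard errors at the fitted parameters."""
    arrays = prepare_arrays(dataset)
    packer = _Packer(result.spec)
    n = len(arrays.respondents)
    d = make_draws(n, 3 if result.spec.latent else 0, packer.S, result.draw_config)
    _, _, scores = _loglik_core(result.pvec, arrays, packer, d, want_scores=True)

    def grad_sum(p):
        _, g, _ = _loglik_core(p, arrays, packer, d)
        return g

    H = _numeric_hessian(grad_sum, result.pvec, step=hessian_step)
    try:
        Hinv = np.linalg.inv(-H)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular Hessian: robust SEs unavailable") from exc
    cov = Hinv @ (scores.T @ scores) @ Hinv
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    result.robust_cov = cov
    result.robust_se = se
    return se


# ---------------------------------------------------------------------------
# Willingness to pay
# ---------------------------------------------------------------------------

def wtp(result: EstimationResult, premium_col: str = "premium",
        min_premium_coef: float = 1e-6) -> pd.DataFrame:
    """WTP_k = -b_k / b_premium per non-premium mean coefficient, delta-method SE.

    Positive WTP for utility-increasing attribute levels, in RMB (premium is
    coded in RMB per year).
    """
    names = result.param_names
    bp = result.get(f"b:{premium_col}")
    if abs(bp) < min_premium_coef:
        raise ValueError("premium coefficient too close to zero: WTP unstable")
    cov = result.robust_cov if result.robust_cov is not None else result.classical_cov
    ip = names.index(f"b:{premium_col}")
    rows = []
    for j, nm in enumerate(names):
        if not nm.startswith("b:") or nm == f"b:{premium_col}":
            continue
        bk = result.pvec[j]
        value = -bk / bp
        se = np.nan
        if cov is not None:
            grad = np.zeros(len(names))
            grad[j] = -1.0 / bp
            grad[ip] = bk / bp**2
            se = float(np.sqrt(grad @ cov @ grad))
        rows.append({"attribute": nm[2:], "wtp": value, "se": se})
    return pd.DataFrame(rows)
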
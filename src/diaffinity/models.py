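"""The Direct Interaction Approximation (DIA) binding free-energy models.

All six models are linear in their fitted coefficients,

    dG = alpha * X_vdw + beta * X_ele + tau * S_x + w * N_rot,

and differ only in how the residue-level interaction sums X_vdw and X_ele
are assembled and which terms are switched on:

========  =======================================================
DIAV      plain residue sums, vacuum electrostatics
DIAS      dielectric-scaled electrostatics; fluctuation damping
          exp(-alpha2*S_vdw(i)), exp(-beta2*S_ele(i)) per residue
DIAV_L    DIAV plus the ligand-entropy term w * N_rot
DIAV_W    DIAV with residue weights exp(gamma * h_w(i))
DIAV_LW   ligand-entropy term plus water-exchange weights
DIAV_LC   ligand-entropy term plus contact-number weights
========  =======================================================

The linear coefficients (alpha, beta, tau, w) are fit by ordinary least
squares with no intercept — the model equations carry no constant term.  The
nonlinear parameters (gamma; alpha2, beta2 for DIAS) are optimized once on
the full training pool against the leave-one-out cross-validated mean
absolute error and held fixed inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MODEL_IDS",
    "REFERENCE_PARAMS",
    "ModelSpec",
    "FittedModel",
    "EvaluationReport",
    "ComplexData",
    "assemble_features",
    "predict_dg",
    "fit_linear",
    "optimize_gamma",
    "fit_dias_exponents",
    "loocv",
    "mean_abs_error",
    "sd_diff",
    "pearson",
    "spearman",
    "consensus_score",
]

MODEL_IDS = ("DIAV", "DIAS", "DIAV_L", "DIAV_W", "DIAV_LW", "DIAV_LC")

#: Cross-validation-average parameter sets from the original 34-complex
#: training set; usable as documented defaults for prediction without a fit.
REFERENCE_PARAMS: dict[str, dict[str, float]] = {
    "DIAV": dict(alpha=0.0341719, beta=0.0017533, tau=-0.0002198, w=0.0),
    "DIAS": dict(alpha=0.0392333, beta=0.0030804, tau=-0.0000053, w=0.0),
    "DIAV_L": dict(alpha=0.0370196, beta=0.0029651, tau=-0.0000050, w=0.1749169),
    "DIAV_W": dict(alpha=0.0346823, beta=0.0021929, tau=-0.0002054, w=0.0),
    "DIAV_LW": dict(alpha=0.0413163, beta=0.0062033, tau=-0.0000067, w=0.1536118, gamma=-6.115),
    "DIAV_LC": dict(alpha=0.0343046, beta=0.0042958, tau=-0.0000070, w=0.1143295, gamma=0.00613),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which terms a DIA model variant switches on."""

    model_id: str
    entropy_channel: str = "DIH"  # "DIH" or "ASA"
    dielectric_exponent: float = 0.6  # DIAS only
    gamma: Optional[float] = None  # None -> to be optimized / unit weights
    alpha2: float = 0.0  # DIAS fluctuation exponents
    beta2: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}; expected one of {MODEL_IDS}")
        if self.entropy_channel not in ("DIH", "ASA"):
            raise ValueError("entropy_channel must be 'DIH' or 'ASA'")
        if self.model_id != "DIAS" and (self.alpha2 != 0.0 or self.beta2 != 0.0):
            raise ValueError("alpha2/beta2 apply to the DIAS model only")

    @property
    def hydration_source(self) -> str:
        if self.model_id in ("DIAV_W", "DIAV_LW"):
            return "water_exchange"
        if self.model_id == "DIAV_LC":
            return "contact"
        return "none"

    @property
    def has_ligand_term(self) -> bool:
        return self.model_id in ("DIAV_L", "DIAV_LW", "DIAV_LC")

    @property
    def uses_modified_electrostatics(self) -> bool:
        return self.model_id == "DIAS"

    @property
    def term_names(self) -> tuple[str, ...]:
        base = ("alpha", "beta", "tau")
        return base + ("w",) if self.has_ligand_term else base


@dataclass
class FittedModel:
    alpha: float
    beta: float
    tau: float
    w: float = 0.0
    alpha2: float = 0.0
    beta2: float = 0.0
    gamma: float = 0.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.alpha, self.beta, self.tau, self.w, self.alpha2, self.beta2, self.gamma]
        if not np.all(np.isfinite(vals)):
            raise ValueError("fitted parameters must be finite")

    def coefficients(self, spec: ModelSpec) -> np.ndarray:
        out = [self.alpha, self.beta, self.tau]
        if spec.has_ligand_term:
            out.append(self.w)
        return np.array(out)


@dataclass
class EvaluationReport:
    """Prediction statistics over a set of complexes."""

    mean_abs_error: float
    sd_diff: float
    pearson_r: float
    spearman_rho: float
    predictions: pd.DataFrame  # complex_id, dg_exptl, dg_pred

    def __post_init__(self) -> None:
        if self.mean_abs_error < 0:
            raise ValueError("mean_abs_error must be non-negative")
        for r in (self.pearson_r, self.spearman_rho):
            if np.isfinite(r) and abs(r) > 1 + 1e-12:
                raise ValueError("correlation out of [-1, 1]")


@dataclass
class ComplexData:
    """Everything the model equations need about one complex.

    Per-residue arrays are ordered identically across fields; hydration
    arrays come from the apo-protein trajectory of the same target.
    """

    complex_id: str
    dg_exptl: float
    e_vdw: np.ndarray  # mean residue-ligand vdW energies
    e_ele: np.ndarray  # mean residue-ligand electrostatic energies
    s_vdw: np.ndarray  # vdW fluctuations
    s_ele: np.ndarray  # electrostatic fluctuations
    h_w: np.ndarray  # water-exchange rates
    h_c: np.ndarray  # contact rates
    s_dih: float = 0.0
    s_asa: float = 0.0
    n_rot: int = 0
    e_ele_mod: Optional[np.ndarray] = None  # dielectric-scaled electrostatics
    docking_score: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.e_vdw)
        for name in ("e_ele", "s_vdw", "s_ele", "h_w", "h_c"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{self.complex_id}: residue array {name!r} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if self.e_ele_mod is not None and len(self.e_ele_mod) != n:
            raise ValueError(f"{self.complex_id}: e_ele_mod length mismatch")

    def to_dict(self) -> dict:
        out = {
            "complex_id": self.complex_id,
            "dg_exptl": self.dg_exptl,
            "s_dih": self.s_dih,
            "s_asa": self.s_asa,
            "n_rot": self.n_rot,
        }
        for name in ("e_vdw", "e_ele", "s_vdw", "s_ele", "h_w", "h_c"):
            out[name] = np.asarray(getattr(self, name), dtype=float).tolist()
        if self.e_ele_mod is not None:
            out["e_ele_mod"] = np.asarray(self.e_ele_mod, dtype=float).tolist()
        if self.docking_score is not None:
            out["docking_score"] = self.docking_score
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ComplexData":
        arrays = {
            k: np.asarray(d[k], dtype=float)
            for k in ("e_vdw", "e_ele", "s_vdw", "s_ele", "h_w", "h_c")
        }
        return cls(
            complex_id=str(d["complex_id"]),
            dg_exptl=float(d["dg_exptl"]),
            s_dih=float(d.get("s_dih", 0.0)),
            s_asa=float(d.get("s_asa", 0.0)),
            n_rot=int(d.get("n_rot", 0)),
            e_ele_mod=None if d.get("e_ele_mod") is None else np.asarray(d["e_ele_mod"], dtype=float),
            docking_score=d.get("docking_score"),
            **arrays,
        )


# ---------------------------------------------------------------------------
# Feature assembly and prediction
# ---------------------------------------------------------------------------

def assemble_features(
    data: ComplexData,
    spec: ModelSpec,
    gamma: Optional[float] = None,
    alpha2: Optional[float] = None,
    beta2: Optional[float] = None,
) -> np.ndarray:
    """Reduce per-residue arrays to the model's linear features.

    Returns (X_vdw, X_ele, S_x) plus N_rot when the ligand term is active:

        X_vdw = sum_i g_i * E_vdw(i) * exp(-alpha2 * S_vdw(i))
        X_ele = sum_i g_i * E~_ele(i) * exp(-beta2 * S_ele(i))

    with g_i = exp(gamma * H_i) for the weighted models (H from the spec's
    hydration source) and E~ the dielectric-scaled electrostatics for DIAS.
    """
    gamma = spec.gamma if gamma is None else gamma
    alpha2 = spec.alpha2 if alpha2 is None else alpha2
    beta2 = spec.beta2 if beta2 is None else beta2
    src = spec.hydration_source
    if src == "water_exchange":
        g = np.exp((gamma or 0.0) * data.h_w)
    elif src == "contact":
        g = np.exp((gamma or 0.0) * data.h_c)
    else:
        g = np.ones_like(data.e_vdw)
    if spec.uses_modified_electrostatics:
        if data.e_ele_mod is None:
            raise ValueError(f"{data.complex_id}: DIAS requires dielectric-scaled electrostatics")
        e_ele = data.e_ele_mod
    else:
        e_ele = data.e_ele
    x_vdw = float(np.sum(g * data.e_vdw * np.exp(-alpha2 * data.s_vdw)))
    x_ele = float(np.sum(g * e_ele * np.exp(-beta2 * data.s_ele)))
    s_x = data.s_dih if spec.entropy_channel == "DIH" else data.s_asa
    feats = [x_vdw, x_ele, s_x]
    if spec.has_ligand_term:
        feats.append(float(data.n_rot))
    return np.array(feats)


def predict_dg(model: FittedModel, features: np.ndarray, spec: ModelSpec) -> float:
    """dG = alpha*X_vdw + beta*X_ele + tau*S_x (+ w*N_rot), kcal/mol."""
    coef = model.coefficients(spec)
    if len(features) != len(coef):
        raise ValueError(f"expected {len(coef)} features, got {len(features)}")
    return float(coef @ np.asarray(features, dtype=float) + model.intercept)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design_matrix(
    dataset: Sequence[ComplexData],
    spec: ModelSpec,
    gamma: Optional[float],
    alpha2: Optional[float],
    beta2: Optional[float],
) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([assemble_features(d, spec, gamma, alpha2, beta2) for d in dataset])
    y = np.array([d.dg_exptl for d in dataset])
    return x, y


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    bad = []
    for k in range(x.shape[1]):
        others = np.delete(x, k, axis=1)
        if others.shape[1] == 0:
            continue
        resid = x[:, k] - others @ np.linalg.lstsq(others, x[:, k], rcond=None)[0]
        scale = np.linalg.norm(x[:, k]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(names[k])
    return bad


def fit_linear(
    dataset: Sequence[ComplexData],
    spec: ModelSpec,
    gamma: Optional[float] = None,
    alpha2: Optional[float] = None,
    beta2: Optional[float] = None,
    intercept: bool = False,
) -> FittedModel:
    """No-intercept ordinary least squares for (alpha, beta, tau[, w]).

    The optional intercept exists for diagnostics only; the model equations
    contain no constant term.
    """
    x, y = _design_matrix(dataset, spec, gamma, alpha2, beta2)
    names = list(spec.term_names)
    if intercept:
        x = np.column_stack([x, np.ones(len(y))])
        names.append("intercept")
    if len(dataset) < x.shape[1]:
        raise ValueError(f"need at least {x.shape[1]} records, got {len(dataset)}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, names) or names
        raise ValueError(f"rank-deficient design matrix; collinear columns: {', '.join(bad)}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    params = dict(zip(names, coef))
    return FittedModel(
        alpha=params["alpha"],
        beta=params["beta"],
        tau=params["tau"],
        w=params.get("w", 0.0),
        alpha2=spec.alpha2 if alpha2 is None else alpha2,
        beta2=spec.beta2 if beta2 is None else beta2,
        gamma=(spec.gamma if gamma is None else gamma) or 0.0,
        intercept=params.get("intercept", 0.0),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def loocv(
    dataset: Sequence[ComplexData],
    spec: ModelSpec,
    gamma: Optional[float] = None,
    alpha2: Optional[float] = None,
    beta2: Optional[float] = None,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Leave-one-out cross-validation with per-fold linear refits.

    The nonlinear parameters (gamma, alpha2, beta2) stay fixed across folds.
    Returns the held-out evaluation report and a per-parameter summary
    (average, SD, min, max, fraction negative) over the fold fits.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 records")
    preds = np.empty(n)
    fold_params: list[dict[str, float]] = []
    for i in range(n):
        train = [d for k, d in enumerate(dataset) if k != i]
        try:
            model = fit_linear(train, spec, gamma, alpha2, beta2)
        except ValueError as exc:
            raise ValueError(f"fold {i} ({dataset[i].complex_id}): {exc}") from exc
        feats = assemble_features(dataset[i], spec, gamma, alpha2, beta2)
        preds[i] = predict_dg(model, feats, spec)
        fold_params.append(
            {name: getattr(model, name) for name in ("alpha", "beta", "tau", "w")}
        )
    obs = np.array([d.dg_exptl for d in dataset])
    report = evaluation_report(
        preds, obs, [d.complex_id for d in dataset]
    )
    pf = pd.DataFrame(fold_params)
    summary = pd.DataFrame(
        {
            "average": pf.mean(),
            "sd": pf.std(ddof=0),
            "min": pf.min(),
            "max": pf.max(),
            "fraction_negative": (pf < 0).mean(),
        }
    )
    return report, summary


def evaluation_report(pred, obs, complex_ids=None) -> EvaluationReport:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ids = list(complex_ids) if complex_ids is not None else list(range(len(obs)))
    return EvaluationReport(
        mean_abs_error=mean_abs_error(pred, obs),
        sd_diff=sd_diff(pred, obs),
        pearson_r=pearson(pred, obs),
        spearman_rho=spearman(pred, obs),
        predictions=pd.DataFrame(
            {"complex_id": ids, "dg_exptl": obs, "dg_pred": pred}
        ),
    )


# ---------------------------------------------------------------------------
# Nonlinear parameter optimization
# ---------------------------------------------------------------------------

def _loocv_mae(dataset, spec, gamma, alpha2, beta2) -> float:
    report, _ = loocv(dataset, spec, gamma, alpha2, beta2)
    if not np.isfinite(report.mean_abs_error):
        raise ValueError("non-finite cross-validation objective")
    return report.mean_abs_error


def optimize_gamma(
    dataset: Sequence[ComplexData],
    spec: ModelSpec,
    bounds: tuple[float, float] = (-20.0, 20.0),
    n_grid: int = 81,
    flat_tol: float = 1e-12,
) -> float:
    """Optimize the residue-weight exponent gamma against the LOOCV error.

    A bracketing grid scan over *bounds* is refined by bounded scalar
    minimization.  A flat objective (e.g., all residues sharing the same H)
    returns 0 — no weighting.
    """
    def safe_mae(g: float) -> float:
        # exp(gamma*H) can overflow for large |gamma| on contact-number
        # scales; such points are simply not candidates
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                report, _ = loocv(dataset, spec, g, None, None)
            mae = report.mean_abs_error
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        return mae if np.isfinite(mae) else np.inf

    lo, hi = bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([safe_mae(float(g)) for g in grid])
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("cross-validation objective non-finite over the whole gamma range")
    if vals[finite].max() - vals[finite].min() < flat_tol:
        return 0.0
    k = int(np.argmin(vals))
    blo, bhi = grid[max(0, k - 1)], grid[min(n_grid - 1, k + 1)]
    res = optimize.minimize_scalar(
        safe_mae, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-4}
    )
    best = float(res.x) if res.fun <= vals[k] else float(grid[k])
    return float(np.clip(best, lo, hi))


def fit_dias_exponents(
    dataset: Sequence[ComplexData],
    spec: ModelSpec,
    x0: tuple[float, float] = (0.0, 0.0),
    grid: tuple[float, float, int] = (-1.0, 2.0, 7),
) -> tuple[float, float]:
    """Derivative-free fit of the DIAS fluctuation exponents (alpha2, beta2).

    A coarse grid scan around the starting point selects the basin for a
    Nelder-Mead refinement; the cross-validated objective is not convex.
    """
    def objective(p):
        return _loocv_mae(dataset, spec, spec.gamma, float(p[0]), float(p[1]))

    lo, hi, k = grid
    candidates = [np.asarray(x0, dtype=float)] + [
        np.array([a, b]) for a in np.linspace(lo, hi, k) for b in np.linspace(lo, hi, k)
    ]
    start = min(candidates, key=objective)
    res = optimize.minimize(
        objective, x0=start, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10},
    )
    if not np.all(np.isfinite(res.x)):
        raise ValueError("non-finite DIAS exponent optimization result")
    # never return a point worse than the start
    if objective(res.x) > objective(np.asarray(x0, dtype=float)):
        return float(x0[0]), float(x0[1])
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

def _check_lengths(pred, obs):
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("pred and obs must be equal-length 1-D vectors")
    return pred, obs


def mean_abs_error(pred, obs) -> float:
    """Mean absolute prediction error, kcal/mol."""
    pred, obs = _check_lengths(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def sd_diff(pred, obs, centered: bool = True) -> float:
    """Spread of the differences (pred - obs), kcal/mol.

    ``centered=True`` (default) is the population standard deviation about
    the mean difference; ``centered=False`` is the uncentered root mean
    square difference, the convention the packaged benchmark tables' SD
    rows follow.
    """
    pred, obs = _check_lengths(pred, obs)
    d = pred - obs
    return float(np.sqrt(np.mean(d**2)) if not centered else np.std(d))


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _check_lengths(x, y)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson requires n >= 2 and nonzero variance in both vectors")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Rank correlation; ties receive average ranks."""
    x, y = _check_lengths(x, y)
    if x.size < 2:
        raise ValueError("spearman requires n >= 2")
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        raise ValueError("spearman undefined (zero rank variance)")
    return float(rho)


def consensus_score(dg_dia: float, docking_score: float) -> float:
    """Simple sum of a DIA-estimated dG and an external docking score."""
    if not (np.isfinite(dg_dia) and np.isfinite(docking_score)):
        raise ValueError("consensus_score requires finite inputs")
    return float(dg_dia + docking_score)
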
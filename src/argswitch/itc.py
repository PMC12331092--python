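"""One-site and two-independent-site binding isotherms for titration calorimetry.

The biphasic titration of a phosphopeptide against arrestin is modelled as
two *independent* classes of sites on the macromolecule, with the high-
affinity class conventionally first (K_D1 ≤ K_D2).  Heats are on the
Wiseman presentation: kcal per mole of injectant versus cumulative molar
ratio, with the usual displacement-dilution bookkeeping of a perfusion
cell (each injection of volume v dilutes prior cell contents by 1 − v/V0).

Free-ligand concentration is closed by mass balance,

    L + M·(n1·L/(K_D1+L) + n2·L/(K_D2+L)) = L_total,

solved by bracketed root finding (the left side is strictly increasing in
L, so the root on [0, L_total] is unique).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats as sps

from .errors import EmptyInputError

__all__ = [
    "BindingParams",
    "ITCExperiment",
    "Isotherm",
    "FitResult",
    "ModelComparison",
    "free_ligand_solve",
    "simulate_isotherm",
    "fit_isotherm",
    "compare_models",
    "read_isotherm_csv",
    "write_isotherm_csv",
]


@dataclass(frozen=True)
class BindingParams:
    """Thermodynamic parameters: K_D in μM, ΔH in kcal per mol of injectant.

    ``kd2=None`` selects a one-site model.  When both sites are present the
    convention is kd1 ≤ kd2 (site I is the high-affinity site).
    """

    kd1: float
    dh1: float
    kd2: float | None = None
    dh2: float = 0.0
    n1: float = 1.0
    n2: float = 1.0
    baseline: float = 0.0  # kcal/mol offset per injection

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or (self.kd2 is not None and self.kd2 <= 0):
            raise ValueError("dissociation constants must be positive")
        if self.n1 <= 0 or (self.kd2 is not None and self.n2 <= 0):
            raise ValueError("stoichiometries must be positive")

    @property
    def two_site(self) -> bool:
        return self.kd2 is not None

    def ordered(self) -> "BindingParams":
        """Sites relabelled so kd1 ≤ kd2."""
        if self.two_site and self.kd2 < self.kd1:
            return replace(
                self, kd1=self.kd2, kd2=self.kd1, dh1=self.dh2, dh2=self.dh1,
                n1=self.n2, n2=self.n1,
            )
        return self


@dataclass(frozen=True)
class ITCExperiment:
    """Cell/syringe geometry and concentrations.

    Defaults reflect a titration of 1 mM peptide into 200 μM arrestin in
    2.5 μL injections at 298 K.
    """

    cell_volume_uL: float = 200.0
    macromolecule_conc_uM: float = 200.0
    syringe_conc_uM: float = 1000.0
    # 40 × 2.5 μL titrates to a cumulative molar ratio ≈ 3 — past the
    # two-site stoichiometry of 2, so the low-affinity phase is covered.
    injection_volumes_uL: tuple[float, ...] = (2.5,) * 40
    temperature_K: float = 298.0

    def __post_init__(self) -> None:
        if (
            self.cell_volume_uL <= 0
            or self.macromolecule_conc_uM <= 0
            or self.syringe_conc_uM < 0
            or any(v <= 0 for v in self.injection_volumes_uL)
        ):
            raise ValueError("volumes and concentrations must be positive")


@dataclass
class Isotherm:
    """Per-injection molar ratio (cumulative ligand/macromolecule) and heat."""

    molar_ratio: np.ndarray  # dimensionless, strictly increasing
    heat: np.ndarray  # kcal per mol of injectant

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat = np.asarray(self.heat, dtype=float)
        if self.molar_ratio.shape != self.heat.shape or self.molar_ratio.ndim != 1:
            raise ValueError("molar_ratio and heat must be equal-length vectors")
        if self.molar_ratio.size == 0:
            raise EmptyInputError("isotherm has no injections")
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")

    def __len__(self) -> int:
        return len(self.heat)


@dataclass
class FitResult:
    params: BindingParams
    ssr: float
    converged: bool
    model: str  # "one_site" | "two_site"
    n_obs: int = 0
    # linearised standard errors of (dh1, dh2); dh2 SE is nan for one-site
    dh_se: tuple[float, float] = (np.nan, np.nan)

    @property
    def n_params(self) -> int:
        return 4 if self.model == "one_site" else 7


@dataclass
class ModelComparison:
    preferred: str  # "one_site" | "two_site"
    f_statistic: float
    p_value: float
    one_site: FitResult
    two_site: FitResult
    no_binding: bool = False


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def free_ligand_solve(
    total_ligand_uM: float, total_macromolecule_uM: float, params: BindingParams
) -> float:
    """Free-ligand concentration (μM) closing the mass balance.

    Bracketed Brent root-finding on [0, L_total]; the balance is strictly
    monotonic in L so the bracket always holds.
    """
    lt, m = float(total_ligand_uM), float(total_macromolecule_uM)
    if lt < 0 or m < 0:
        raise ValueError("totals must be non-negative")
    if lt == 0.0:
        return 0.0
    if m == 0.0:
        return lt

    def balance(l_free: float) -> float:
        bound = params.n1 * l_free / (params.kd1 + l_free)
        if params.two_site:
            bound += params.n2 * l_free / (params.kd2 + l_free)
        return l_free + m * bound - lt

    if balance(lt) <= 0.0:  # numerically saturated: all ligand free-side root at lt
        return lt
    return float(optimize.brentq(balance, 0.0, lt, xtol=1e-15, rtol=1e-14))


def _free_ligand_vec(
    l_total: np.ndarray, m: np.ndarray, params: BindingParams, n_iter: int = 30
) -> np.ndarray:
    """Vectorized bisection + Newton polish of the mass balance.

    The balance is strictly increasing in L so the bracket [0, L_total]
    cannot fail; 30 halvings localise the root to ~1e-9 relative and four
    Newton steps finish to machine precision.
    """
    lo = np.zeros_like(l_total)
    hi = l_total.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        bound = params.n1 * mid / (params.kd1 + mid)
        if params.two_site:
            bound = bound + params.n2 * mid / (params.kd2 + mid)
        too_high = mid + m * bound > l_total
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    x = 0.5 * (lo + hi)
    # Newton polish: the balance is smooth and strictly increasing, so a few
    # steps from the bisection estimate reach machine precision.
    for _ in range(4):
        f = x + m * params.n1 * x / (params.kd1 + x) - l_total
        fp = 1.0 + m * params.n1 * params.kd1 / (params.kd1 + x) ** 2
        if params.two_site:
            f = f + m * params.n2 * x / (params.kd2 + x)
            fp = fp + m * params.n2 * params.kd2 / (params.kd2 + x) ** 2
        x = np.clip(x - f / fp, lo, hi)
    return x


def simulate_isotherm(exp: ITCExperiment, params: BindingParams) -> Isotherm:
    """Forward-model the per-injection heats (kcal/mol injectant).

    Displacement-dilution bookkeeping: injection i of volume v_i dilutes the
    prior cell contents by (1 − v_i/V0); the observed incremental heat adds
    back half of the displaced volume's heat content,
    q_i = [Q_i − Q_{i−1} + (v_i/V0)·(Q_i + Q_{i−1})/2] / n_injected.
    """
    v0 = exp.cell_volume_uL
    v0_L = v0 * 1e-9  # μL → L
    v = np.asarray(exp.injection_volumes_uL, dtype=float)
    # Dilution recursion is independent of the binding model: precompute
    # per-injection totals, then close the mass balance for all injections
    # at once.
    d = np.cumprod(1.0 - v / v0)
    m = exp.macromolecule_conc_uM * d  # total macromolecule, μM
    l_cell = np.empty_like(v)
    l_prev = 0.0
    for i, (vi, di) in enumerate(zip(v, 1.0 - v / v0)):
        l_prev = l_prev * di + (vi / v0) * exp.syringe_conc_uM
        l_cell[i] = l_prev
    l_free = _free_ligand_vec(l_cell, m, params)

    theta = params.n1 * l_free / (params.kd1 + l_free) * params.dh1
    if params.two_site:
        theta = theta + params.n2 * l_free / (params.kd2 + l_free) * params.dh2
    q = v0_L * (m * 1e-6) * theta  # cumulative heat content, kcal
    q_prev = np.concatenate([[0.0], q[:-1]])
    moles_injected = v * 1e-9 * exp.syringe_conc_uM * 1e-6  # mol
    dq = q - q_prev + (v / v0) * 0.5 * (q + q_prev)
    with np.errstate(divide="ignore", invalid="ignore"):
        heats = np.where(
            moles_injected > 0, dq / moles_injected + params.baseline, params.baseline
        )
        ratios = np.where(m > 0, l_cell / m, np.inf)
    if exp.syringe_conc_uM == 0.0:
        # degenerate blank titration: use the injection index as abscissa
        ratios = np.arange(1.0, len(v) + 1.0)
    return Isotherm(molar_ratio=ratios, heat=heats)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pack(params: BindingParams, model: str) -> np.ndarray:
    if model == "one_site":
        return np.array([np.log(params.kd1), params.dh1, params.n1, params.baseline])
    return np.array(
        [
            np.log(params.kd1),
            np.log(params.kd2),
            params.dh1,
            params.dh2,
            params.n1,
            params.n2,
            params.baseline,
        ]
    )


def _unpack(vec: np.ndarray, model: str) -> BindingParams:
    if model == "one_site":
        return BindingParams(
            kd1=float(np.exp(vec[0])), dh1=float(vec[1]), n1=float(vec[2]),
            baseline=float(vec[3]),
        )
    return BindingParams(
        kd1=float(np.exp(vec[0])), kd2=float(np.exp(vec[1])),
        dh1=float(vec[2]), dh2=float(vec[3]),
        n1=float(vec[4]), n2=float(vec[5]), baseline=float(vec[6]),
    )


def _initial_guesses(
    iso: Isotherm, exp: ITCExperiment, model: str
) -> list[BindingParams]:
    """Multi-start initialisation.

    Baseline from the titration tail, ΔH from plateau heights, K_D seeded
    from the cell concentration (the steepest-descent molar ratio marks the
    equivalence point; the K_D scale around it is set by c = M/K_D ≈ 10)
    and jittered ×/÷3 and ×/÷9 for 8 starts.  Biphasic curves have local
    minima, hence the spread.
    """
    heat = iso.heat
    baseline = float(np.mean(heat[-3:])) if len(heat) >= 3 else float(heat[-1])
    dh_first = float(heat[0] - baseline)
    if dh_first == 0.0:
        dh_first = -1.0
    mid = len(heat) // 2
    dh_mid = float(heat[mid] - baseline)
    kd_scale = exp.macromolecule_conc_uM / 10.0
    jitters = [1.0, 3.0, 1 / 3.0, 9.0, 1 / 9.0, 27.0, 1 / 27.0, 81.0]
    guesses = []
    for j in jitters:
        if model == "one_site":
            guesses.append(
                BindingParams(
                    kd1=kd_scale * j, dh1=dh_first, n1=1.0, baseline=baseline
                )
            )
        else:
            guesses.append(
                BindingParams(
                    kd1=kd_scale * j / 3.0,
                    kd2=kd_scale * j * 3.0,
                    dh1=dh_first,
                    dh2=dh_mid if dh_mid != 0.0 else dh_first / 2.0,
                    n1=1.0,
                    n2=1.0,
                    baseline=baseline,
                )
            )
    return guesses


# Physically motivated fit bounds: K_D within what titration calorimetry at
# μM cell concentrations can resolve, |ΔH| below typical protein–peptide
# magnitudes, and a bounded per-injection baseline.  These exclude
# degenerate enthalpy/baseline-cancellation minima.
_BOUND_LOG_KD = (np.log(1e-4), np.log(1e4))  # μM
_BOUND_N = (0.05, 5.0)
_BOUND_DH = (-50.0, 50.0)  # kcal/mol
_BOUND_BASELINE = (-5.0, 5.0)  # kcal/mol


def _fit_bounds(model: str) -> tuple[np.ndarray, np.ndarray]:
    if model == "one_site":
        lo = [_BOUND_LOG_KD[0], _BOUND_DH[0], _BOUND_N[0], _BOUND_BASELINE[0]]
        hi = [_BOUND_LOG_KD[1], _BOUND_DH[1], _BOUND_N[1], _BOUND_BASELINE[1]]
    else:
        lo = (
            [_BOUND_LOG_KD[0]] * 2 + [_BOUND_DH[0]] * 2
            + [_BOUND_N[0]] * 2 + [_BOUND_BASELINE[0]]
        )
        hi = (
            [_BOUND_LOG_KD[1]] * 2 + [_BOUND_DH[1]] * 2
            + [_BOUND_N[1]] * 2 + [_BOUND_BASELINE[1]]
        )
    return np.asarray(lo), np.asarray(hi)


def fit_isotherm(iso: Isotherm, exp: ITCExperiment, model: str = "two_site") -> FitResult:
    """Nonlinear least squares of the forward model against observed heats.

    Multi-start (8 initialisations); the best-SSR solution is reported with
    the kd1 ≤ kd2 site convention enforced.  ``converged`` is False only if
    every start fails.
    """
    if model not in ("one_site", "two_site"):
        raise ValueError(f"unknown model {model!r}")
    n_free = 4 if model == "one_site" else 7
    if len(iso) < 2 * n_free:
        raise ValueError(
            f"{model} fit needs ≥ {2 * n_free} injections, got {len(iso)}"
        )

    observed = iso.heat
    if len(observed) != len(exp.injection_volumes_uL):
        raise ValueError(
            "isotherm length does not match the experiment's injection schedule"
        )

    def residuals(vec: np.ndarray) -> np.ndarray:
        return simulate_isotherm(exp, _unpack(vec, model)).heat - observed

    lo, hi = _fit_bounds(model)
    best = None  # (ssr, raw solution vector, success, jacobian)
    for guess in _initial_guesses(iso, exp, model):
        x0 = np.clip(_pack(guess, model), lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        ssr = float(np.sum(res.fun ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x, bool(res.success), res.jac)
    if best is None:
        raise RuntimeError("all fit starts failed")
    ssr, x, success, jac = best

    # Linearised parameter covariance for the enthalpy standard errors
    # (used as the model-selection noise floor).
    dof = max(len(iso) - n_free, 1)
    s2 = ssr / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_free, np.nan)
    if model == "one_site":
        dh_se = (float(se[1]), np.nan)
    else:
        dh_se = (float(se[2]), float(se[3]))

    params = _unpack(x, model)
    if params.two_site and params.kd2 < params.kd1:
        params = params.ordered()
        dh_se = (dh_se[1], dh_se[0])
    return FitResult(
        params=params, ssr=ssr, converged=success, model=model,
        n_obs=len(iso), dh_se=dh_se,
    )


def compare_models(
    iso: Isotherm,
    exp: ITCExperiment,
    alpha: float = 0.05,
    dh_floor: float | None = None,
) -> ModelComparison:
    """Extra-sum-of-squares F test, two-site (7 params) vs one-site (4 params).

    Two-site is preferred only when the F test rejects at ``alpha`` AND both
    site enthalpies exceed the noise floor.  The floor is per-parameter:
    each |ΔH| must exceed twice its linearised standard error (spurious
    splits of a single site leave the extra enthalpy poorly determined, so
    this gate removes most F-test false positives), with a small absolute
    floor.  Pass ``dh_floor`` to use a fixed kcal/mol floor instead.
    Near-zero enthalpy everywhere flags "no binding".
    """
    fit1 = fit_isotherm(iso, exp, "one_site")
    fit2 = fit_isotherm(iso, exp, "two_site")
    n = len(iso)
    df_extra = fit2.n_params - fit1.n_params
    df_resid = n - fit2.n_params
    if df_resid <= 0:
        raise ValueError("too few injections for the model comparison")
    denom = fit2.ssr / df_resid
    if denom <= 0:
        denom = np.finfo(float).tiny
    f_stat = max(0.0, (fit1.ssr - fit2.ssr) / df_extra) / denom
    p = float(sps.f.sf(f_stat, df_extra, df_resid))

    rmse2 = np.sqrt(fit2.ssr / df_resid)
    abs_floor = max(3.0 * rmse2, 1e-3)
    if dh_floor is not None:
        floors = (dh_floor, dh_floor)
    else:
        floors = tuple(
            max(2.0 * se, abs_floor) if np.isfinite(se) else abs_floor
            for se in fit2.dh_se
        )
    both_dh_real = (
        abs(fit2.params.dh1) > floors[0] and abs(fit2.params.dh2) > floors[1]
    )
    preferred = "two_site" if (p < alpha and both_dh_real) else "one_site"
    chosen = fit2 if preferred == "two_site" else fit1
    no_binding = abs(chosen.params.dh1) <= abs_floor and (
        not chosen.params.two_site or abs(chosen.params.dh2) <= abs_floor
    )
    return ModelComparison(
        preferred=preferred,
        f_statistic=float(f_stat),
        p_value=p,
        one_site=fit1,
        two_site=fit2,
        no_binding=no_binding,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_isotherm_csv(path: str, ucal: bool = False) -> tuple[Isotherm, np.ndarray]:
    """Read an injection table: injection, volume_uL, molar_ratio, heat.

    The heat column is ``heat_kcal_per_mol`` (or ``heat_ucal`` with
    ``ucal=True``, converted per mole of injectant by the caller's schedule).
    Returns the isotherm and the per-injection volumes.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("injection", "volume_uL", "molar_ratio"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    heat_col = "heat_ucal" if ucal else "heat_kcal_per_mol"
    if heat_col not in df.columns:
        raise ValueError(f"{path}: missing required column {heat_col!r}")
    df = df.sort_values("injection")
    heats = df[heat_col].to_numpy(dtype=float)
    volumes = df["volume_uL"].to_numpy(dtype=float)
    if ucal:
        # μcal → kcal (1e-9), per mole of injectant in each injection
        raise NotImplementedError(
            "raw μcal conversion requires the syringe concentration; "
            "pre-normalise to kcal/mol instead"
        )
    return Isotherm(
        molar_ratio=df["molar_ratio"].to_numpy(dtype=float), heat=heats
    ), volumes


def write_isotherm_csv(iso: Isotherm, exp: ITCExperiment, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "injection": np.arange(1, len(iso) + 1),
            "volume_uL": np.asarray(exp.injection_volumes_uL)[: len(iso)],
            "molar_ratio": iso.molar_ratio,
            "heat_kcal_per_mol": iso.heat,
        }
    ).to_csv(path, index=False)
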
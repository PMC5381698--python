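"""Scalar biophysical models: crystal metrics, kinetics fits, melt curves.

Three independent calculation families live here:

* **Crystal metrics** — triclinic unit-cell volume, the Matthews coefficient
  V_M = V_cell / (Z · M) in Å³/Da, and the solvent fraction
  V_s = (1 − 1.230/V_M) · 100 %.  The constant 1.230 Å³·Da⁻¹ is the
  reciprocal of 0.813·10⁻³ (the conventional protein partial specific volume
  of 0.74 cm³/g expressed per dalton per Å³).
* **Enzyme kinetics** — least-squares fits of the Michaelis–Menten equation
  v = V_max·x/(K_m + x) and the Hill equation v = V_max·x^H/(K^H + x^H)
  (K reported as K_0.5), with an extra-sum-of-squares F-test deciding whether
  the cooperative model is justified.  Hill fits are initialization-sensitive,
  so the fit multi-starts from H ∈ {0.5, 1, 2, 4}.
* **Thermofluor melts** — min–max normalization of the fluorescence signal to
  [0, 1] followed by a Boltzmann sigmoid fit F(T) = 1/(1 + exp((T_m − T)/s));
  the inflection point is the melting temperature T_m.  The default
  normalization uses the pre-/post-transition plateau means (first and last
  five points) to resist spikes; plain global min/max is available.

Fitting is delegated to :mod:`lmfit` (Levenberg–Marquardt least squares with
parameter bounds and standard errors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy import stats

__all__ = [
    "UnitCell",
    "CrystalMetrics",
    "KineticsDataset",
    "KineticsFit",
    "ModelComparison",
    "MeltFit",
    "cell_volume",
    "matthews",
    "molar_mass_from_sequence",
    "fit_kinetics",
    "compare_kinetic_models",
    "fit_melt",
    "MATTHEWS_SOLVENT_CONSTANT",
]

from .structure_io import UnitCell  # re-exported: shared with Assembly metadata

#: 1/ (0.813e-3) convention: partial specific volume 0.74 cm³/g per Å³/Da.
MATTHEWS_SOLVENT_CONSTANT = 1.230


def cell_volume(cell: UnitCell) -> float:
    """Triclinic unit-cell volume V = abc·√(1 − Σcos² + 2·cosα·cosβ·cosγ), Å³."""
    ca, cb, cg = (
        math.cos(math.radians(cell.alpha)),
        math.cos(math.radians(cell.beta)),
        math.cos(math.radians(cell.gamma)),
    )
    radicand = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if radicand <= 0.0:
        raise ValueError(
            f"cell angles ({cell.alpha}, {cell.beta}, {cell.gamma}) do not "
            "define a valid cell (non-positive volume radicand)"
        )
    return cell.a * cell.b * cell.c * math.sqrt(radicand)


@dataclass
class CrystalMetrics:
    cell_volume: float  # Å³
    n_molecules_per_cell: int  # Z
    molar_mass: float  # Da
    matthews_vm: float  # Å³/Da
    solvent_fraction: float | None  # %; None when V_M <= 1.230
    warnings: list[str] = field(default_factory=list)


def matthews(cell: UnitCell, z_molecules: int, molar_mass: float) -> CrystalMetrics:
    """Matthews coefficient and solvent content for a crystal form.

    Nothing is rounded here; presentation layers round.  A V_M at or below
    the protein-volume constant leaves the solvent fraction undefined
    (flagged), not negative.
    """
    if z_molecules < 1:
        raise ValueError("Z must be >= 1")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    vol = cell_volume(cell)
    vm = vol / (z_molecules * molar_mass)
    warns: list[str] = []
    solvent: float | None = (1.0 - MATTHEWS_SOLVENT_CONSTANT / vm) * 100.0
    if vm <= MATTHEWS_SOLVENT_CONSTANT:
        solvent = None
        warns.append(
            f"V_M = {vm:.3f} Å³/Da <= {MATTHEWS_SOLVENT_CONSTANT}: solvent "
            "content undefined (cell cannot hold Z protein molecules)"
        )
    return CrystalMetrics(
        cell_volume=vol,
        n_molecules_per_cell=z_molecules,
        molar_mass=molar_mass,
        matthews_vm=vm,
        solvent_fraction=solvent,
        warnings=warns,
    )


def molar_mass_from_sequence(sequence: str) -> float:
    """Average-isotope molar mass of a protein chain in Da (one water per chain)."""
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    valid = set("ACDEFGHIKLMNPQRSTVWY")
    bad = sorted(set(seq) - valid)
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {bad}")
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


# ---------------------------------------------------------------------------
# Kinetics


@dataclass
class KineticsDataset:
    substrate_conc: np.ndarray  # mM
    velocity: np.ndarray  # rate units (unit-agnostic)
    fixed_substrate: str = ""  # metadata: the co-substrate held saturating

    def __post_init__(self) -> None:
        x = np.asarray(self.substrate_conc, dtype=float)
        y = np.asarray(self.velocity, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("substrate_conc and velocity must be equal-length 1-D")
        if np.any(x < 0):
            raise ValueError("substrate concentrations must be >= 0")
        self.substrate_conc, self.velocity = x, y

    def __len__(self) -> int:
        return len(self.substrate_conc)


def _mm_model(x: np.ndarray, v_max: float, k: float) -> np.ndarray:
    return v_max * x / (k + x)


def _hill_model(x: np.ndarray, v_max: float, k: float, h: float) -> np.ndarray:
    xs = np.where(x > 0, x, np.finfo(float).tiny)
    return v_max * xs**h / (k**h + xs**h)


@dataclass
class KineticsFit:
    model: str  # {MM, Hill}
    v_max: float
    k: float  # K_m (MM) or K_0.5 (Hill), mM
    hill_h: float | None  # None for MM
    stderr: dict[str, float | None]
    rss: float
    n_points: int
    converged: bool
    n_params: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "MM":
            return _mm_model(x, self.v_max, self.k)
        return _hill_model(x, self.v_max, self.k, self.hill_h)


def _initial_k(x: np.ndarray, y: np.ndarray) -> float:
    """x at half-maximal velocity, by linear interpolation on sorted data."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = ys.max() / 2.0
    above = np.nonzero(ys >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return float(max(np.median(xs[xs > 0]) if np.any(xs > 0) else 1.0, 1e-6))
    i = above[0]
    x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_kinetics(data: KineticsDataset, model: str = "MM") -> KineticsFit:
    """Least-squares fit of the Michaelis–Menten or Hill equation.

    Requires at least five points spanning at least two distinct
    concentrations.  Initialization: V_max₀ = 1.2·max(v), K₀ from the
    half-maximal concentration by interpolation, and (Hill only) a multi-start
    over H₀ ∈ {0.5, 1, 2, 4} keeping the lowest residual sum of squares.
    """
    if model not in ("MM", "Hill"):
        raise ValueError(f"unknown kinetic model {model!r}")
    x, y = data.substrate_conc, data.velocity
    if len(x) < 5:
        raise ValueError(f"need >= 5 data points, got {len(x)}")
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct substrate concentrations")

    v0 = float(max(y.max(), np.finfo(float).tiny)) * 1.2
    k0 = _initial_k(x, y)

    def run(h0: float | None) -> lmfit.minimizer.MinimizerResult | None:
        params = lmfit.Parameters()
        params.add("v_max", value=v0, min=np.finfo(float).tiny)
        params.add("k", value=k0, min=np.finfo(float).tiny)
        if h0 is not None:
            params.add("h", value=h0, min=1e-3, max=50.0)

        def resid(p):
            if h0 is None:
                return _mm_model(x, p["v_max"].value, p["k"].value) - y
            return _hill_model(x, p["v_max"].value, p["k"].value, p["h"].value) - y

        try:
            return lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            return None

    if model == "MM":
        results = [run(None)]
    else:
        results = [run(h0) for h0 in (0.5, 1.0, 2.0, 4.0)]
    results = [r for r in results if r is not None and np.isfinite(r.chisqr)]
    if not results:
        raise RuntimeError(
            f"{model} fit failed to converge from any start "
            f"(n={len(x)}, v range {y.min():.3g}-{y.max():.3g})"
        )
    best = min(results, key=lambda r: r.chisqr)
    p = best.params
    stderr = {name: (p[name].stderr if p[name].stderr else None) for name in p}
    return KineticsFit(
        model=model,
        v_max=float(p["v_max"].value),
        k=float(p["k"].value),
        hill_h=float(p["h"].value) if model == "Hill" else None,
        stderr=stderr,
        rss=float(best.chisqr),
        n_points=len(x),
        converged=bool(best.success),
        n_params=3 if model == "Hill" else 2,
    )


@dataclass
class ModelComparison:
    preferred: str  # {MM, Hill}
    f_statistic: float
    p_value: float
    fit_mm: KineticsFit
    fit_hill: KineticsFit


def compare_kinetic_models(
    data: KineticsDataset, alpha: float = 0.05
) -> ModelComparison:
    """Extra-sum-of-squares F-test of Hill (3 parameters) vs nested MM (2).

    The Hill model is preferred only when the RSS reduction is significant at
    ``alpha`` — formalizing the visual "obvious deviation from hyperbolic
    kinetics" call.
    """
    fit_mm = fit_kinetics(data, "MM")
    fit_hill = fit_kinetics(data, "Hill")
    n = len(data)
    df_extra = fit_hill.n_params - fit_mm.n_params
    df_resid = n - fit_hill.n_params
    if df_resid <= 0:
        raise ValueError("too few points for the F-test")
    rss_drop = max(fit_mm.rss - fit_hill.rss, 0.0)
    if fit_hill.rss <= 0:
        f_stat = math.inf if rss_drop > 0 else 0.0
        p = 0.0 if rss_drop > 0 else 1.0
    else:
        f_stat = (rss_drop / df_extra) / (fit_hill.rss / df_resid)
        p = float(stats.f.sf(f_stat, df_extra, df_resid))
    return ModelComparison(
        preferred="Hill" if p < alpha else "MM",
        f_statistic=float(f_stat),
        p_value=p,
        fit_mm=fit_mm,
        fit_hill=fit_hill,
    )


# ---------------------------------------------------------------------------
# Thermofluor melt curves


@dataclass
class MeltFit:
    t_m: float  # °C, inflection point
    slope: float  # °C, sigmoid width (> 0)
    stderr: dict[str, float | None]
    rss: float
    normalized: np.ndarray  # signal after normalization to [0, 1]
    converged: bool


def _normalize_melt(signal: np.ndarray, mode: str, n_plateau: int = 5) -> np.ndarray:
    if mode == "plateau":
        low = float(np.mean(signal[:n_plateau]))
        high = float(np.mean(signal[-n_plateau:]))
    elif mode == "minmax":
        low, high = float(signal.min()), float(signal.max())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if high <= low:
        raise ValueError(
            "melt signal shows no rise between the low and high plateaus "
            "(non-sigmoidal data)"
        )
    return (signal - low) / (high - low)


def fit_melt(
    temperatures: np.ndarray,
    fluorescence: np.ndarray,
    normalization: str = "plateau",
) -> MeltFit:
    """Boltzmann sigmoid fit of a thermal-unfolding fluorescence curve.

    The signal is normalized to [0, 1] (``"plateau"``: mean of the first/last
    five points; ``"minmax"``: global extrema) and fitted to
    F(T) = 1/(1 + exp((T_m − T)/slope)).  T_m, the inflection point, must land
    inside the measured temperature range; a signal with no rise raises.
    """
    T = np.asarray(temperatures, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.shape != F.shape or T.ndim != 1:
        raise ValueError("temperatures and fluorescence must be equal-length 1-D")
    if len(T) < 10:
        raise ValueError(f"need >= 10 points, got {len(T)}")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    norm = _normalize_melt(F, normalization)

    # initial T_m: first crossing of 0.5
    above = np.nonzero(norm >= 0.5)[0]
    tm0 = float(T[above[0]]) if len(above) else float(T[len(T) // 2])

    params = lmfit.Parameters()
    params.add("t_m", value=tm0, min=float(T[0]), max=float(T[-1]))
    params.add("slope", value=max((T[-1] - T[0]) / 20.0, 0.1), min=1e-3)

    def resid(p):
        return 1.0 / (1.0 + np.exp((p["t_m"].value - T) / p["slope"].value)) - norm

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    fitted = 1.0 / (1.0 + np.exp((p["t_m"].value - T) / p["slope"].value))
    rise = float(fitted[-1] - fitted[0])
    if rise < 0.2:
        raise ValueError("fitted curve shows no transition inside the range")
    return MeltFit(
        t_m=float(p["t_m"].value),
        slope=float(p["slope"].value),
        stderr={name: (p[name].stderr if p[name].stderr else None) for name in p},
        rss=float(result.chisqr),
        normalized=norm,
        converged=bool(result.success),
    )
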
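"""Equilibrium binding math: steady-state/direct 1:1 fits, single-point
competition Kd, coupled two-ligand equilibria and LN1/LN2 preference ratios.

Model
-----
Direct titrations (biolayer-interferometry equilibrium responses, or
fluorescence-anisotropy direct binding) follow the 1:1 hyperbola

    A = A0 + Amax * [L] / (Kd + [L])

with A0 fixed at zero in BLI mode (responses are baseline-subtracted nm
shifts) and floated in FP mode.

The fluorescence-polarization competition assay measures the anisotropy
of a fixed fluorescent probe (P) bound to the galectin (G) in the
presence of one competitor concentration (C). The competitor Kd follows
from five closed-form steps of mass-action algebra:

    [PG] = (A_competitor - A0) / (Amax - A0) * [P]_total
    [P]  = [P]_total - [PG]
    [G]  = Kd_probe * [PG] / [P]
    [CG] = [G]_total - [PG] - [G]
    [C]  = [C]_total - [CG]
    Kd_competitor = [C] * [G] / [CG]

All concentrations are in uM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .errors import FitError, InconsistentInputsError, NoCompetitionError

# Convention note: the preference ratio below is computed as
# Kd(LN2)/Kd(LN1) so that values above 1 mark type-1-LacNAc-preferring
# lectins; the published summary table labels its column Kd_LN1/Kd_LN2
# but its printed numbers follow the Kd_LN2/Kd_LN1 arithmetic, and this
# implementation reproduces the printed numbers.
RATIO_CONVENTION = {
    "formula": "Kd_LN2 / Kd_LN1",
    "interpretation": "ratio > 1 means LN1-preferred",
    "note": (
        "the source table's footnote states Kd_LN1/Kd_LN2, which is "
        "inconsistent with every printed value; the printed-value "
        "convention is used here"
    ),
}


@dataclass
class TitrationData:
    """An equilibrium titration: analyte concentrations vs responses."""

    concentrations: np.ndarray  # uM
    responses: np.ndarray  # nm shift (BLI) or anisotropy (FP)
    response_type: str = "bli"  # "bli" | "fp"

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise FitError("concentrations and responses differ in length")
        if self.concentrations.size < 4:
            raise FitError("need at least 4 titration points")
        if np.any(self.concentrations < 0):
            raise FitError("negative concentrations")
        if self.response_type not in ("bli", "fp"):
            raise FitError(f"unknown response_type '{self.response_type}'")


@dataclass(frozen=True)
class KdResult:
    kd: float  # uM
    kd_stderr: float | None
    amax_fit: float
    a0_fit: float | None
    method: str  # "bli_steady_state" | "fp_direct" | "fp_competition"
    flags: tuple[str, ...] = ()
    species: dict | None = None

    def __post_init__(self):
        if not (self.kd > 0):
            raise FitError(f"non-positive Kd {self.kd}")


def _hyperbola(c, kd, amax, a0):
    return a0 + amax * c / (kd + c)


def _jacobian(c, kd, amax, a0):
    denom = kd + c
    d_kd = -amax * c / denom**2
    d_amax = c / denom
    d_a0 = np.ones_like(c)
    return np.stack([d_kd, d_amax, d_a0], axis=1)


def fit_saturation(t: TitrationData) -> KdResult:
    """Fit the 1:1 saturation hyperbola by nonlinear least squares.

    BLI mode fixes the baseline A0 at zero; FP mode floats it. The fit is
    multistarted from Kd equal to the smallest, geometric-mean and largest
    positive concentration to avoid local minima; the reported standard
    error is the asymptotic (covariance-based) one.
    """
    c, a = t.concentrations, t.responses
    pos = c[c > 0]
    if pos.size == 0 or pos.max() / pos.min() < 10:
        raise FitError("concentrations must span at least a 10-fold range")
    fix_a0 = t.response_type == "bli"
    amax0 = float(np.max(a) - (0.0 if fix_a0 else np.min(a))) or 1.0
    a0_0 = 0.0 if fix_a0 else float(np.min(a))
    starts = [float(pos.min()), float(np.exp(np.mean(np.log(pos)))), float(pos.max())]

    if fix_a0:
        model = lambda cc, kd, amax: _hyperbola(cc, kd, amax, 0.0)
        jac = lambda cc, kd, amax: _jacobian(cc, kd, amax, 0.0)[:, :2]
        p_extra: list[float] = []
    else:
        model = _hyperbola
        jac = _jacobian
        p_extra = [a0_0]

    best = None
    for kd0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, c, a, p0=[kd0, amax0] + p_extra, jac=jac,
                    maxfev=10000,
                    bounds=([1e-12, -np.inf] + [-np.inf] * len(p_extra),
                            [np.inf] * (2 + len(p_extra))),
                )
        except (RuntimeError, ValueError):
            continue
        resid = a - model(c, *popt)
        ssr = float(resid @ resid)
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError("saturation fit did not converge from any start")
    ssr, popt, pcov = best
    kd = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None

    flags = []
    # responses should rise with concentration; a drop exceeding a fifth
    # of the dynamic range is beyond plausible assay noise
    order = np.argsort(c)
    span = float(np.ptp(a))
    drops = np.diff(a[order])
    if span > 0 and np.any(drops < -0.2 * span):
        flags.append("nonmonotone_responses")
    return KdResult(
        kd=kd,
        kd_stderr=stderr,
        amax_fit=float(popt[1]),
        a0_fit=None if fix_a0 else float(popt[2]),
        method="bli_steady_state" if fix_a0 else "fp_direct",
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# competition


@dataclass
class CompetitionMeasurement:
    """One FP competition point plus the assay constants it needs."""

    a_competitor: float
    a0: float
    a_max: float
    kd_probe: float  # uM
    p_total: float  # uM
    g_total: float  # uM
    c_total: float  # uM

    def __post_init__(self):
        if not (self.a0 <= self.a_competitor <= self.a_max):
            raise InconsistentInputsError(
                f"anisotropy {self.a_competitor} outside [{self.a0}, {self.a_max}]"
            )
        for name in ("kd_probe", "p_total", "g_total", "c_total"):
            if getattr(self, name) <= 0:
                raise InconsistentInputsError(f"{name} must be positive")


def competition_kd(m: CompetitionMeasurement) -> KdResult:
    """Closed-form competitor Kd from one competition measurement.

    Applies the five mass-action steps in order (see module docstring).
    Raises :class:`NoCompetitionError` when the deduced competitor-bound
    concentration is not positive (competitor too weak to detect) and
    :class:`InconsistentInputsError` when the free-competitor
    concentration comes out non-positive.
    """
    if not (m.a0 < m.a_competitor < m.a_max):
        raise InconsistentInputsError(
            "a_competitor must lie strictly between a0 and a_max"
        )
    frac = (m.a_competitor - m.a0) / (m.a_max - m.a0)
    pg = frac * m.p_total
    p = m.p_total - pg
    g = m.kd_probe * pg / p
    cg = m.g_total - pg - g
    if cg <= 0:
        raise NoCompetitionError(
            f"[CG] = {cg:.4g} uM <= 0: no detectable competition"
        )
    cfree = m.c_total - cg
    if cfree <= 0:
        raise InconsistentInputsError(
            f"free competitor [C] = {cfree:.4g} uM <= 0; inputs inconsistent"
        )
    kd = cfree * g / cg
    species = {"PG": pg, "P": p, "G": g, "CG": cg, "C": cfree}
    # mass balances hold by construction; assert to guard refactors
    assert abs(m.p_total - (p + pg)) < 1e-9 * max(m.p_total, 1.0)
    assert abs(m.c_total - (cfree + cg)) < 1e-9 * max(m.c_total, 1.0)
    return KdResult(
        kd=float(kd),
        kd_stderr=None,
        amax_fit=m.a_max,
        a0_fit=m.a0,
        method="fp_competition",
        species=species,
    )


@dataclass(frozen=True)
class EquilibriumState:
    """Exact species concentrations of one receptor + two ligands."""

    p_free: float
    g_free: float
    c_free: float
    pg: float
    cg: float
    anisotropy: float


def simulate_equilibrium_competition(
    kd_probe: float,
    kd_comp: float,
    p_total: float,
    g_total: float,
    c_total: float,
    a0: float = 0.05,
    a_max: float = 0.25,
) -> EquilibriumState:
    """Solve the coupled mass-action equilibria P+G<->PG, C+G<->CG exactly.

    Root-finds the free-galectin concentration on [0, g_total] (the
    balance function is monotone, so the root is unique) and derives all
    species; the anisotropy is a0 + (a_max - a0) * [PG]/[P]_total.
    ``c_total = 0`` reduces to the single-ligand closed form.
    """
    for name, v in (("kd_probe", kd_probe), ("kd_comp", kd_comp),
                    ("p_total", p_total), ("g_total", g_total)):
        if v <= 0:
            raise InconsistentInputsError(f"{name} must be positive")
    if c_total < 0:
        raise InconsistentInputsError("c_total must be non-negative")

    def balance(g):
        return (
            g
            + p_total * g / (kd_probe + g)
            + c_total * g / (kd_comp + g)
            - g_total
        )

    if balance(g_total) <= 0:  # only possible at p_total = c_total = 0
        g = g_total
    else:
        g = brentq(balance, 0.0, g_total, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    pg = p_total * g / (kd_probe + g)
    cg = c_total * g / (kd_comp + g)
    state = EquilibriumState(
        p_free=p_total - pg,
        g_free=g,
        c_free=c_total - cg,
        pg=pg,
        cg=cg,
        anisotropy=a0 + (a_max - a0) * pg / p_total,
    )
    # conservation to solver precision
    assert abs(g + pg + cg - g_total) < 1e-8 * max(g_total, 1.0)
    return state


# ---------------------------------------------------------------------------
# preference ratios and the published dissociation constants


def preference_ratio(kd_ln1: float, kd_ln2: float) -> float:
    """LN1/LN2 preference ratio: Kd(LN2)/Kd(LN1), > 1 iff LN1-preferred.

    See :data:`RATIO_CONVENTION` for why the arithmetic runs LN2 over LN1.
    """
    if kd_ln1 <= 0 or kd_ln2 <= 0:
        raise InconsistentInputsError("dissociation constants must be positive")
    return float(kd_ln2) / float(kd_ln1)


# Published dissociation constants (uM) for the three wild-type human
# galectins and the galectin-3 E165A mutant, as printed: BLI steady-state
# values at 300 K and FP-competition values at 277 K. These are measured
# inputs (the raw assay data are not deposited), used for the ratio
# arithmetic; galkit does not recompute them.
PUBLISHED_KD = pd.DataFrame(
    [
        {"protein": "hGal1", "method": "bli", "kd_ln1": 340.0, "kd_ln2": 150.0,
         "kd_ln1_err": None, "kd_ln2_err": None},
        {"protein": "hGal1", "method": "fp", "kd_ln1": 6.74, "kd_ln2": 3.59,
         "kd_ln1_err": 3.14, "kd_ln2_err": 2.35},
        {"protein": "hGal3", "method": "bli", "kd_ln1": 93.0, "kd_ln2": 33.0,
         "kd_ln1_err": None, "kd_ln2_err": None},
        {"protein": "hGal3", "method": "fp", "kd_ln1": 1.44, "kd_ln2": 0.33,
         "kd_ln1_err": 0.28, "kd_ln2_err": 0.064},
        {"protein": "hGal7", "method": "bli", "kd_ln1": 270.0, "kd_ln2": 410.0,
         "kd_ln1_err": None, "kd_ln2_err": None},
        {"protein": "hGal7", "method": "fp", "kd_ln1": 6.63, "kd_ln2": 19.69,
         "kd_ln1_err": 1.27, "kd_ln2_err": 3.45},
        {"protein": "hGal3-E165A", "method": "bli", "kd_ln1": 230.0,
         "kd_ln2": 280.0, "kd_ln1_err": None, "kd_ln2_err": None},
    ]
)
PUBLISHED_KD.attrs["units"] = "uM"
PUBLISHED_KD.attrs["source"] = "published measurements (inputs, not computed)"


def published_kd(protein: str, method: str) -> tuple[float, float]:
    """Return the published (Kd_LN1, Kd_LN2) pair in uM."""
    row = PUBLISHED_KD[
        (PUBLISHED_KD.protein == protein) & (PUBLISHED_KD.method == method)
    ]
    if row.empty:
        raise KeyError(f"no published Kd for ({protein}, {method})")
    r = row.iloc[0]
    return float(r.kd_ln1), float(r.kd_ln2)


def preference_ratio_table() -> pd.DataFrame:
    """Preference ratios computed from the published Kd values, rounded to
    two decimals (the summary-table precision)."""
    rows = []
    for r in PUBLISHED_KD.itertuples():
        rows.append(
            {
                "protein": r.protein,
                "method": r.method,
                "ratio": round(preference_ratio(r.kd_ln1, r.kd_ln2), 2),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["convention"] = RATIO_CONVENTION
    return df


# FP-competition assay stoichiometries (uM): probe, galectin, competitor.
ASSAY_PRESETS = {
    "hGal1": {"p_total": 0.1, "g_total": 120.0, "c_total": 300.0},
    "hGal3": {"p_total": 0.1, "g_total": 3.0, "c_total": 6.0},
    "hGal7": {"p_total": 0.1, "g_total": 120.0, "c_total": 300.0},
}
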
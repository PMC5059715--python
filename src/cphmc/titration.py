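"""Titration analysis: Hill fits, conditional pKa's, net-charge curves.

The central object is the titration curve S(pH), the deprotonated
(unprotonated) fraction of a site per pH condition, fitted to the
generalized Henderson-Hasselbalch form

    S(pH) = 1 / (1 + 10^{n (pKa - pH)})

where n is the Hill coefficient (n = 1 for an independent site).  A
*macroscopic* pKa uses all frames; *microscopic* pKa's condition the frames
on a per-frame boolean (here typically: sodium bound to a core aspartate),
which decomposes the macroscopic curve into a frame-count-weighted mixture
of the conditional curves — an identity that holds exactly by counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import ProtonationEnsemble

__all__ = [
    "TitrationCurve",
    "PKaFit",
    "titration_curve",
    "fit_hill",
    "conditional_pka",
    "net_charge_curve",
    "reconstruct_net_charge",
    "find_sign_switch_ph",
    "occupancy_vs_deprotonation",
    "hill_curve",
]


def hill_curve(ph, pka: float, n: float = 1.0):
    """Generalized Henderson-Hasselbalch unprotonated fraction."""
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


@dataclass(frozen=True)
class TitrationCurve:
    """Unprotonated fraction S per pH, with frame counts.

    ``omitted_ph`` lists ladder points dropped because no frame satisfied
    the conditioning predicate there.
    """

    ph: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    site: str = ""
    omitted_ph: tuple[float, ...] = ()

    def __post_init__(self):
        ph = np.asarray(self.ph, dtype=float)
        s = np.asarray(self.s, dtype=float)
        counts = np.asarray(self.counts)
        if not (len(ph) == len(s) == len(counts)):
            raise ValueError("ph, s and counts must have equal length")
        if len(ph) > 1 and not np.all(np.diff(ph) > 0):
            raise ValueError("pH values must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("unprotonated fractions must lie in [0, 1]")
        if np.any(counts < 0):
            raise ValueError("frame counts must be non-negative")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class PKaFit:
    """Result of a generalized Henderson-Hasselbalch fit.

    ``incomplete_titration`` is set when the curve never reaches S >= 0.9 or
    never drops to S <= 0.1 over the sampled ladder, i.e. the apparent pKa
    extrapolates beyond the well-constrained range.
    """

    pka: float
    hill_n: float
    residual_norm: float
    incomplete_titration: bool
    n_points: int

    def predict(self, ph):
        return hill_curve(ph, self.pka, self.hill_n)


def _resolve_condition(
    ensemble: ProtonationEnsemble,
    condition: str | np.ndarray | Callable[[pd.DataFrame], np.ndarray] | None,
) -> np.ndarray | None:
    if condition is None:
        return None
    if isinstance(condition, str):
        col = condition if condition in ensemble.data.columns else f"occ:{condition}"
        if col not in ensemble.data.columns:
            raise KeyError(f"condition column {condition!r} not in ensemble")
        return ensemble.data[col].to_numpy().astype(bool)
    if callable(condition):
        mask = np.asarray(condition(ensemble.data)).astype(bool)
    else:
        mask = np.asarray(condition).astype(bool)
    if mask.shape[0] != len(ensemble.data):
        raise ValueError(
            f"condition length {mask.shape[0]} does not match frame count {len(ensemble.data)}"
        )
    return mask


def titration_curve(
    ensemble: ProtonationEnsemble,
    site: str,
    condition: str | np.ndarray | Callable | None = None,
) -> TitrationCurve:
    """Per-pH unprotonated fraction of ``site``, optionally over the frames
    satisfying ``condition`` (a bit-column name, boolean array or callable).

    pH points where no frame satisfies the condition are omitted from the
    curve and recorded in ``omitted_ph``; if every point is empty this is an
    error.
    """
    col = site if site in ensemble.data.columns else f"site:{site}"
    if col not in ensemble.data.columns:
        raise KeyError(f"unknown site {site!r}; valid: {list(ensemble.bit_labels)}")
    mask = _resolve_condition(ensemble, condition)
    df = ensemble.data if mask is None else ensemble.data[mask]
    ph_all = sorted(ensemble.data["pH"].unique())
    grp = df.groupby("pH", sort=True)[col].agg(["mean", "count"])
    kept = [p for p in ph_all if p in grp.index and grp.loc[p, "count"] > 0]
    omitted = tuple(p for p in ph_all if p not in kept)
    if not kept:
        raise ValueError(
            f"no frames satisfy the condition at any pH for site {site!r} "
            f"(ladder: {ph_all})"
        )
    return TitrationCurve(
        ph=np.array(kept, dtype=float),
        s=grp.loc[kept, "mean"].to_numpy(dtype=float),
        counts=grp.loc[kept, "count"].to_numpy(),
        site=site,
        omitted_ph=omitted,
    )


def fit_hill(
    curve: TitrationCurve,
    fix_n: bool = False,
    pka_bounds: tuple[float, float] | None = None,
    n_bounds: tuple[float, float] = (0.2, 4.0),
) -> PKaFit:
    """Weighted least-squares fit of the generalized Henderson-Hasselbalch
    equation to a titration curve.

    Points are weighted by the square root of their frame counts (so the
    uneven counts that arise under conditioning are handled consistently).
    Default pKa bounds are the sampled pH range widened by 2 units on each
    side; the Hill coefficient is bounded in ``n_bounds`` or fixed at 1.
    Raises on fewer than 4 points or on a degenerate (constant) curve.
    """
    ph, s, counts = curve.ph, curve.s, curve.counts
    if len(ph) < 4:
        raise ValueError(f"need >= 4 pH points to fit, got {len(ph)}")
    if np.ptp(s) < 1e-12:
        raise ValueError("degenerate titration curve: S is constant, no pKa is identifiable")
    if pka_bounds is None:
        pka_bounds = (float(ph.min()) - 2.0, float(ph.max()) + 2.0)

    # initial guess: midpoint crossing, n = 1
    above = s >= 0.5
    if above.any() and not above.all():
        k = int(np.argmax(above))
        if k == 0:
            pka0 = float(ph[0])
        else:
            f0, f1 = s[k - 1], s[k]
            pka0 = float(ph[k - 1] + (0.5 - f0) / (f1 - f0) * (ph[k] - ph[k - 1]))
    else:
        pka0 = float(ph[np.argmin(np.abs(s - 0.5))])
    pka0 = float(np.clip(pka0, *pka_bounds))

    w = np.sqrt(np.maximum(counts.astype(float), 1.0))
    sigma = 1.0 / w
    if fix_n:
        popt, _ = curve_fit(
            lambda x, pka: hill_curve(x, pka, 1.0),
            ph, s, p0=[pka0], sigma=sigma, absolute_sigma=False,
            bounds=([pka_bounds[0]], [pka_bounds[1]]), maxfev=10000,
        )
        pka, n = float(popt[0]), 1.0
    else:
        popt, _ = curve_fit(
            hill_curve, ph, s, p0=[pka0, 1.0], sigma=sigma, absolute_sigma=False,
            bounds=([pka_bounds[0], n_bounds[0]], [pka_bounds[1], n_bounds[1]]),
            maxfev=10000,
        )
        pka, n = float(popt[0]), float(popt[1])

    resid = float(np.linalg.norm((s - hill_curve(ph, pka, n)) * w) / np.linalg.norm(w))
    incomplete = bool(s.max() < 0.9 or s.min() > 0.1)
    return PKaFit(pka=pka, hill_n=n, residual_norm=resid,
                  incomplete_titration=incomplete, n_points=len(ph))


@dataclass(frozen=True)
class ConditionalPKa:
    """Microscopic/macroscopic pKa decomposition for one site.

    When the condition (or its complement) holds in no frame at all, the
    corresponding curve and fit are None and the macroscopic fit coincides
    with the surviving branch.
    """

    fit_given: PKaFit | None
    fit_not: PKaFit | None
    fit_macroscopic: PKaFit
    curve_given: TitrationCurve | None
    curve_not: TitrationCurve | None
    curve_macroscopic: TitrationCurve
    condition_frequency: pd.Series
    mixture_residual: float


def conditional_pka(
    ensemble: ProtonationEnsemble,
    site: str,
    condition: str | np.ndarray | Callable,
    fix_n: bool = False,
) -> ConditionalPKa:
    """Fit the site's titration conditioned on a per-frame boolean, on its
    complement, and on all frames.

    Also verifies the mixture identity
    ``S_macro(pH) = f(pH) S_given(pH) + (1 - f(pH)) S_not(pH)`` where f is
    the per-pH condition frequency; its maximum absolute residual is
    reported (it is a counting identity, so it should be ~machine epsilon).
    """
    mask = _resolve_condition(ensemble, condition)
    if mask is None:
        raise ValueError("conditional_pka requires a condition")
    curve_m = titration_curve(ensemble, site)
    try:
        curve_g = titration_curve(ensemble, site, mask)
    except ValueError:
        curve_g = None
    try:
        curve_n = titration_curve(ensemble, site, ~mask)
    except ValueError:
        curve_n = None

    df = ensemble.data.assign(_cond=mask)
    freq = df.groupby("pH", sort=True)["_cond"].mean()

    def _s_at(curve: TitrationCurve | None, ph: float) -> float:
        if curve is None:
            return 0.0
        hits = np.nonzero(np.isclose(curve.ph, ph))[0]
        return float(curve.s[hits[0]]) if len(hits) else 0.0

    resid = 0.0
    for i, ph in enumerate(curve_m.ph):
        f = float(freq.loc[ph])
        mix = f * _s_at(curve_g, ph) + (1.0 - f) * _s_at(curve_n, ph)
        resid = max(resid, abs(curve_m.s[i] - mix))

    return ConditionalPKa(
        fit_given=None if curve_g is None else fit_hill(curve_g, fix_n=fix_n),
        fit_not=None if curve_n is None else fit_hill(curve_n, fix_n=fix_n),
        fit_macroscopic=fit_hill(curve_m, fix_n=fix_n),
        curve_given=curve_g,
        curve_not=curve_n,
        curve_macroscopic=curve_m,
        condition_frequency=freq,
        mixture_residual=float(resid),
    )


def net_charge_curve(
    ensemble: ProtonationEnsemble,
    residue_set: Sequence[str],
    fixed_charges: Mapping[str, int] | None = None,
    site_kinds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pH mean and RMSF of the instantaneous net charge of a residue set.

    ``residue_set`` names titratable sites (their per-frame charge follows
    the deprotonation bit and the acid/base kind from ``site_kinds``, or the
    residue-type prefix Asp/Glu = acid, His/Lys = base); ``fixed_charges``
    adds constant contributions.  The RMSF (population std over frames) is
    the error-bar statistic used for charge-vs-pH curves.
    """
    fixed_charges = dict(fixed_charges or {})
    kinds = dict(site_kinds or {})
    acid_prefix = ("Asp", "Glu", "ASP", "GLU")

    charge = np.zeros(len(ensemble.data))
    for name in residue_set:
        col = name if name in ensemble.data.columns else f"site:{name}"
        if col not in ensemble.data.columns:
            valid = [c.split(":", 1)[1] for c in ensemble.bit_labels if c.startswith("site:")]
            raise KeyError(f"unknown residue {name!r}; valid sites: {valid}")
        d = ensemble.data[col].to_numpy()
        kind = kinds.get(name, "acid" if name.startswith(acid_prefix) else "base")
        charge += -d.astype(float) if kind == "acid" else (1.0 - d)
    charge += float(sum(fixed_charges.values()))

    df = pd.DataFrame({"pH": ensemble.data["pH"], "charge": charge})
    out = df.groupby("pH", sort=True)["charge"].agg(
        mean="mean", rmsf=lambda c: float(np.sqrt(np.mean((c - c.mean()) ** 2)))
    )
    return out.reset_index()


def reconstruct_net_charge(
    pka_table: Mapping[str, tuple[float, str]],
    fixed_charges: Mapping[str, int],
    ph: float | np.ndarray,
):
    """Expected net charge from independent-site titration at printed pKa's.

    Each acid contributes ``-1/(1 + 10^{pKa - pH})`` (its mean charge), each
    base its protonated fraction ``1/(1 + 10^{pH - pKa})``; fixed charges add
    as constants.  Assumes Hill n = 1 per site.
    """
    ph = np.asarray(ph, dtype=float)
    total = np.zeros_like(ph, dtype=float)
    for name, entry in pka_table.items():
        try:
            pka, kind = entry
        except (TypeError, ValueError) as exc:
            raise ValueError(f"pka_table entry for {name!r} must be (pKa, kind)") from exc
        if kind == "acid":
            total += -hill_curve(ph, pka)
        elif kind == "base":
            total += 1.0 - hill_curve(ph, pka)
        else:
            raise ValueError(f"residue {name!r}: kind must be 'acid' or 'base', got {kind!r}")
    total += float(sum(fixed_charges.values()))
    return float(total) if total.ndim == 0 else total


def find_sign_switch_ph(ph_grid: np.ndarray, charge: np.ndarray) -> float | None:
    """Smallest pH where the charge curve crosses zero from + to -, by
    linear interpolation between grid points; None if it never does."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    charge = np.asarray(charge, dtype=float)
    if len(ph_grid) != len(charge):
        raise ValueError("grid and charge arrays must have equal length")
    for i in range(len(ph_grid) - 1):
        c0, c1 = charge[i], charge[i + 1]
        if c0 == 0.0 and (i == 0 or charge[i - 1] > 0):
            return float(ph_grid[i])
        if c0 > 0.0 >= c1:
            return float(ph_grid[i] + c0 / (c0 - c1) * (ph_grid[i + 1] - ph_grid[i]))
    return None


@dataclass(frozen=True)
class OccupancyCorrelation:
    """Per-pH (site deprotonated fraction, flag occupancy) points with the
    least-squares line and Pearson correlation across pH conditions."""

    deprotonated_fraction: np.ndarray
    occupancy: np.ndarray
    ph: np.ndarray
    slope: float
    intercept: float
    pearson_r: float
    degenerate: bool


def occupancy_vs_deprotonation(
    ensemble: ProtonationEnsemble, flag: str, site: str
) -> OccupancyCorrelation:
    """Relate a conformational flag's occupancy to a site's deprotonation.

    One point per pH condition; reports the linear fit and Pearson r.  If
    either series is constant across pH the correlation is undefined and the
    result is flagged ``degenerate`` with nan statistics.
    """
    flag_col = flag if flag in ensemble.data.columns else f"flag:{flag}"
    if flag_col not in ensemble.data.columns:
        raise KeyError(f"unknown flag {flag!r}; valid: {list(ensemble.bit_labels)}")
    frac = ensemble.marginal(site)
    occ = ensemble.data.groupby("pH", sort=True)[flag_col].mean()
    x = frac.to_numpy(dtype=float)
    y = occ.to_numpy(dtype=float)
    ph = frac.index.to_numpy(dtype=float)
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        return OccupancyCorrelation(x, y, ph, np.nan, np.nan, np.nan, True)
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return OccupancyCorrelation(x, y, ph, float(slope), float(intercept), r, False)


def pka_table(
    ensemble: ProtonationEnsemble,
    sites: Sequence[str] | None = None,
    condition: str | None = None,
    fix_n: bool = False,
) -> pd.DataFrame:
    """Summarise fitted pKa's for many sites as a tidy table.

    With ``condition``, adds microscopic pKa columns for the condition and
    its complement.  Sites whose curves are degenerate (never titrate on the
    ladder) are reported with NaN pKa rather than raising.
    """
    if sites is None:
        sites = [c.split(":", 1)[1] for c in ensemble.bit_labels if c.startswith("site:")]
    rows = []
    for site in sites:
        row: dict = {"site": site}
        try:
            fit = fit_hill(titration_curve(ensemble, site), fix_n=fix_n)
            row.update(
                pka=fit.pka, hill_n=fit.hill_n, residual=fit.residual_norm,
                incomplete_titration=fit.incomplete_titration,
            )
        except ValueError:
            row.update(pka=np.nan, hill_n=np.nan, residual=np.nan, incomplete_titration=True)
        if condition is not None:
            try:
                cp = conditional_pka(ensemble, site, condition, fix_n=fix_n)
                row.update(
                    pka_given=cp.fit_given.pka if cp.fit_given else np.nan,
                    pka_not=cp.fit_not.pka if cp.fit_not else np.nan,
                    incomplete_given=cp.fit_given.incomplete_titration if cp.fit_given else True,
                    incomplete_not=cp.fit_not.incomplete_titration if cp.fit_not else True,
                )
            except ValueError:
                row.update(pka_given=np.nan, pka_not=np.nan,
                           incomplete_given=True, incomplete_not=True)
        rows.append(row)
    return pd.DataFrame(rows)
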
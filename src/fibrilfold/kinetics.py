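"""ThT fibrillization-kinetics analysis.

Thioflavin T fluorescence reports amyloid mass over time; a plate-reader
time course per well is background-subtracted (mean of the first five
raw readings), then fit by Levenberg–Marquardt least squares to the
Gompertz sigmoid

    y(t) = A * exp(-exp(-(t - t_i) / B))

with A the amplitude (RFU), t_i the inflection time (h) and B the time
constant (h).  The apparent elongation rate is k_app = 1/B and the
half-maximal time follows in closed form as t_half = t_i - B * ln(ln 2).
Aggregation propensity is reported as 1 / t_half.

Quality control discards wells whose raw signal never reaches 50 RFU or
whose fit MSE exceeds one standard deviation of the per-curve maximum
ThT signal within the condition group — both patterns are typical of
bubbles or empty wells.  Either defect alone discards a curve.

A seeded simulator generates replicate wells on the standard 5-minute /
24-hour design for parameter-recovery testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model

LN_LN2 = float(np.log(np.log(2.0)))  # ≈ -0.3665


def gompertz(t: np.ndarray, A: float, t_i: float, B: float) -> np.ndarray:
    """Gompertz sigmoid A * exp(-exp(-(t - t_i)/B))."""
    return A * np.exp(-np.exp(-(np.asarray(t, dtype=float) - t_i) / B))


@dataclass
class ThTCurve:
    """One well's fluorescence time course (time in hours, signal in RFU)."""

    well_id: str
    condition: str
    time: np.ndarray
    rfu: np.ndarray
    background_subtracted: bool = False
    raw_max: float | None = None
    has_missing: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.time.shape != self.rfu.shape:
            raise ValueError(f"well {self.well_id}: time/rfu length mismatch")
        if len(self.time) < 6:
            raise ValueError(
                f"well {self.well_id}: need >= 6 points (5 background + fit)"
            )
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"well {self.well_id}: time not strictly increasing")
        if self.raw_max is None:
            self.raw_max = float(np.nanmax(self.rfu))


@dataclass
class GompertzFit:
    """Fitted Gompertz parameters and derived kinetics for one well."""

    well_id: str
    condition: str
    A: float
    t_i: float
    B: float
    mse: float
    converged: bool
    message: str = ""

    @property
    def k_app(self) -> float:
        """Apparent elongation rate 1/B (h^-1)."""
        return 1.0 / self.B

    @property
    def t_half(self) -> float:
        """Half-amplitude time t_i - B*ln(ln 2) (h)."""
        return self.t_i - self.B * LN_LN2


def subtract_background(curve: ThTCurve) -> ThTCurve:
    """Subtract the mean of the first five raw readings from the whole curve.

    Guarded against double subtraction; the raw maximum is retained for
    the low-signal QC rule.  Pairwise differences between time points
    are unchanged, so curve shape is preserved.
    """
    if curve.background_subtracted:
        raise ValueError(f"well {curve.well_id}: background already subtracted")
    if len(curve.rfu) < 5:
        raise ValueError(f"well {curve.well_id}: need >= 5 points for background")
    background = float(np.mean(curve.rfu[:5]))
    return replace(
        curve,
        rfu=curve.rfu - background,
        background_subtracted=True,
        raw_max=float(np.nanmax(curve.rfu)),
    )


def fit_gompertz(curve: ThTCurve) -> GompertzFit:
    """Levenberg–Marquardt fit of the Gompertz sigmoid to one curve.

    Initialization: A0 = max signal, t_i0 = time of steepest observed
    increase, B0 = (time span)/10.  Non-convergence is reported via
    ``converged=False`` with the optimizer message, never silently.
    """
    if not curve.background_subtracted:
        raise ValueError(f"well {curve.well_id}: subtract background before fitting")
    t, y = curve.time, curve.rfu
    if np.any(~np.isfinite(y)):
        raise ValueError(f"well {curve.well_id}: non-finite values; cannot fit")
    if len(t) < 4:
        raise ValueError(f"well {curve.well_id}: fewer points than parameters")
    if np.allclose(y, 0.0):
        raise ValueError(f"well {curve.well_id}: all-zero curve; nothing to fit")
    a0 = float(np.max(y))
    slope = np.diff(y) / np.diff(t)
    ti0 = float(t[int(np.argmax(slope))])
    b0 = float((t[-1] - t[0]) / 10.0)
    model = Model(gompertz)
    params = model.make_params(A=a0, t_i=ti0, B=b0)
    try:
        result = model.fit(y, params, t=t, method="leastsq")
    except Exception as exc:  # optimizer blew up: report, don't raise
        return GompertzFit(
            curve.well_id, curve.condition,
            A=a0, t_i=ti0, B=b0, mse=float("inf"),
            converged=False, message=str(exc),
        )
    resid = result.best_fit - y
    mse = float((resid**2).sum() / len(y))
    ok = bool(result.success) and result.params["B"].value > 0 and result.params["A"].value > 0
    return GompertzFit(
        curve.well_id,
        curve.condition,
        A=float(result.params["A"].value),
        t_i=float(result.params["t_i"].value),
        B=float(result.params["B"].value),
        mse=mse,
        converged=ok,
        message=str(result.message),
    )


@dataclass
class QCReport:
    """Per-well keep/discard verdicts with reason codes and thresholds."""

    verdicts: dict[str, str]  # well_id -> "keep" | "discard"
    reasons: dict[str, list[str]]  # well_id -> subset of {low_signal, high_mse}
    thresholds: dict[str, object]

    def kept(self) -> list[str]:
        return [w for w, v in self.verdicts.items() if v == "keep"]

    def discarded(self) -> list[str]:
        return [w for w, v in self.verdicts.items() if v == "discard"]


def qc_filter(
    curves: Sequence[ThTCurve],
    fits: Mapping[str, GompertzFit],
    min_raw_rfu: float = 50.0,
    mse_sd_scale: float = 1.0,
) -> QCReport:
    """Discard wells with low raw signal or anomalously poor fits.

    A well is discarded if its raw maximum RFU is below ``min_raw_rfu``
    OR its fit MSE exceeds ``mse_sd_scale`` standard deviations of the
    per-curve maximum ThT signal within its condition group (either
    defect alone suffices; both reasons are recorded when both hold).
    Groups with a single curve skip the MSE criterion with a warning.
    """
    missing = [c.well_id for c in curves if c.well_id not in fits]
    if missing:
        raise ValueError(f"no fit provided for wells: {missing}")
    by_condition: dict[str, list[ThTCurve]] = {}
    for c in curves:
        by_condition.setdefault(c.condition, []).append(c)
    mse_cut: dict[str, float | None] = {}
    for cond, group in by_condition.items():
        if len(group) < 2:
            warnings.warn(
                f"condition {cond!r} has a single curve; MSE criterion skipped"
            )
            mse_cut[cond] = None
            continue
        maxima = np.array([float(np.nanmax(c.rfu)) for c in group])
        mse_cut[cond] = mse_sd_scale * float(np.std(maxima, ddof=1))
    verdicts: dict[str, str] = {}
    reasons: dict[str, list[str]] = {}
    for c in sorted(curves, key=lambda c: c.well_id):
        why: list[str] = []
        if c.raw_max is not None and c.raw_max < min_raw_rfu:
            why.append("low_signal")
        cut = mse_cut[c.condition]
        if cut is not None and fits[c.well_id].mse > cut:
            why.append("high_mse")
        verdicts[c.well_id] = "discard" if why else "keep"
        reasons[c.well_id] = why
    return QCReport(
        verdicts=verdicts,
        reasons=reasons,
        thresholds={
            "min_raw_rfu": min_raw_rfu,
            "mse_sd_scale": mse_sd_scale,
            "mse_cut_per_condition": mse_cut,
        },
    )


def aggregation_propensity(
    fit: GompertzFit | None = None,
    curve: ThTCurve | None = None,
    mode: str = "analytic",
) -> float:
    """Inverse half-time 1/t_half (h^-1).

    ``analytic`` uses the fitted closed form t_i - B*ln(ln 2);
    ``interpolated`` finds the half-maximum crossing of the observed
    background-subtracted curve by linear interpolation.
    """
    if mode == "analytic":
        if fit is None:
            raise ValueError("analytic mode needs a GompertzFit")
        t_half = fit.t_half
    elif mode == "interpolated":
        if curve is None:
            raise ValueError("interpolated mode needs a ThTCurve")
        if not curve.background_subtracted:
            raise ValueError("interpolated mode needs a background-subtracted curve")
        t_half = interpolated_t_half(curve)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if t_half <= 0:
        raise ValueError(f"unphysical t_half={t_half:.4g} h")
    return 1.0 / t_half


def interpolated_t_half(curve: ThTCurve) -> float:
    """First crossing of half the observed maximum, linearly interpolated."""
    y, t = curve.rfu, curve.time
    half = float(np.nanmax(y)) / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) == 0:
        raise ValueError(f"well {curve.well_id}: curve never reaches half-maximum")
    k = int(above[0])
    if k == 0:
        return float(t[0])
    y0, y1 = y[k - 1], y[k]
    t0, t1 = t[k - 1], t[k]
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def simulate_tht(
    A: float,
    t_i: float,
    B: float,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    n_points: int = 289,
    dt: float = 5.0 / 60.0,
    n_replicates: int = 1,
    seed: int | None = None,
    condition: str = "sim",
) -> list[ThTCurve]:
    """Simulate replicate ThT wells on the 5-min / 24-h plate design.

    rfu = baseline + Gompertz(t) + N(0, noise_sd); each replicate draws
    from an independent child stream of the seed, so the full replicate
    set is reproducible and wells are mutually independent.
    """
    if A <= 0 or B <= 0 or n_points < 6 or dt <= 0 or n_replicates < 1:
        raise ValueError("invalid simulation parameters")
    t = np.arange(n_points) * dt
    clean = baseline + gompertz(t, A, t_i, B)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    curves = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        noise = rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else 0.0
        curves.append(
            ThTCurve(
                well_id=f"{condition}_{r + 1:02d}",
                condition=condition,
                time=t,
                rfu=clean + noise,
            )
        )
    return curves


def load_plate(
    path: str | Path,
    layout: str = "wide",
    time_unit: str = "h",
    condition_map: Mapping[str, str] | None = None,
) -> list[ThTCurve]:
    """Load a delimited plate export into per-well curves.

    ``wide``: a time column (named ``time``, case-insensitive) plus one
    column per well.  ``long``: columns time, well, rfu.  Separator is
    sniffed from the extension (.tsv → tab, else comma).  Times are
    normalized to hours.  Wells with missing values are flagged, not
    interpolated.  ``condition_map`` assigns wells to condition labels;
    unmapped wells get their own id as condition.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if time_unit not in ("min", "h"):
        raise ValueError(f"time_unit must be 'min' or 'h', got {time_unit!r}")
    scale = 1.0 / 60.0 if time_unit == "min" else 1.0
    condition_map = dict(condition_map or {})

    def make_curve(well: str, t: np.ndarray, y: np.ndarray) -> ThTCurve:
        t = np.asarray(t, dtype=float) * scale
        y = np.asarray(y, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {well}: time not strictly increasing")
        has_missing = bool(np.any(~np.isfinite(y)))
        curve = ThTCurve(
            well_id=well,
            condition=condition_map.get(well, well),
            time=t,
            rfu=y,
            has_missing=has_missing,
        )
        if has_missing:
            warnings.warn(f"well {well}: missing values flagged, not interpolated")
        return curve

    if layout == "wide":
        time_cols = [c for c in df.columns if str(c).strip().lower() == "time"]
        if not time_cols:
            raise ValueError(f"{path}: no 'time' column in wide layout")
        tcol = time_cols[0]
        wells = [c for c in df.columns if c != tcol]
        seen: set[str] = set()
        for w in wells:
            base = str(w).split(".")[0]
            if base in seen:
                raise ValueError(f"{path}: duplicated well id {base!r}")
            seen.add(base)
        return [make_curve(str(w), df[tcol].to_numpy(), df[w].to_numpy()) for w in wells]
    if layout == "long":
        required = {"time", "well", "rfu"}
        cols = {str(c).strip().lower(): c for c in df.columns}
        if not required <= set(cols):
            raise ValueError(f"{path}: long layout needs columns {sorted(required)}")
        curves = []
        for well, group in df.groupby(cols["well"], sort=True):
            if (group[cols["time"]].duplicated()).any():
                raise ValueError(f"{path}: duplicated time points in well {well!r}")
            g = group.sort_values(cols["time"])
            curves.append(
                make_curve(str(well), g[cols["time"]].to_numpy(), g[cols["rfu"]].to_numpy())
            )
        return curves
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def fits_to_table(
    fits: Iterable[GompertzFit], report: QCReport | None = None
) -> pd.DataFrame:
    """Per-well fit table: well, condition, A, t_i, B, k_app, t_half, mse, verdict."""
    rows = []
    for f in fits:
        rows.append(
            {
                "well": f.well_id,
                "condition": f.condition,
                "A": f.A,
                "t_i": f.t_i,
                "B": f.B,
                "k_app": f.k_app,
                "t_half": f.t_half,
                "mse": f.mse,
                "converged": f.converged,
                "verdict": report.verdicts.get(f.well_id, "keep") if report else "keep",
            }
        )
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame) -> dict:
    """Mean ± sd of k_app and propensity per condition over kept wells."""
    kept = table[table["verdict"] == "keep"]
    out: dict[str, dict[str, float]] = {}
    for cond, group in kept.groupby("condition"):
        propensity = 1.0 / group["t_half"]
        out[str(cond)] = {
            "n": int(len(group)),
            "k_app_mean": float(group["k_app"].mean()),
            "k_app_sd": float(group["k_app"].std(ddof=1)) if len(group) > 1 else float("nan"),
            "propensity_mean": float(propensity.mean()),
            "propensity_sd": float(propensity.std(ddof=1)) if len(group) > 1 else float("nan"),
        }
    return out


def plot_fits(
    curves: Sequence[ThTCurve],
    fits: Mapping[str, GompertzFit],
    out_path: str | Path,
) -> list[Path]:
    """Overlay observed curves and fitted sigmoids; writes PNG and SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        ax.plot(c.time, c.rfu, lw=0.8, alpha=0.6, label=f"{c.well_id} data")
        f = fits.get(c.well_id)
        if f is not None:
            ax.plot(c.time, gompertz(c.time, f.A, f.t_i, f.B), lw=1.4, ls="--")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ThT fluorescence (RFU, background-subtracted)")
    if len(curves) <= 10:
        ax.legend(fontsize=7)
    written = []
    base = out_path.with_suffix("")
    for suffix in (".png", ".svg"):
        target = base.with_suffix(suffix)
        fig.savefig(target, dpi=150, bbox_inches="tight")
        written.append(target)
    plt.close(fig)
    return written
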
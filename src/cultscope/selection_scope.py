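"""Multilevel-selection boundary condition and the summary figures.

A group-beneficial but individually costly practice can spread by
cultural group selection only when

    group benefit / individual cost > (1 - F_ST) / F_ST,

so ``(1 - F_ST) / F_ST`` is the minimum benefit-to-cost ratio compatible
with spread at the observed differentiation.  The threshold diverges as
F_ST approaches 0 (identical groups leave nothing for group selection to
act on) and falls to 0 at F_ST = 1 (with completely differentiated
groups any group benefit suffices).

Because Likert means are ordinal they cannot form valid benefit/cost
ratios; the scope figure therefore places each practice ON the boundary
curve at its observed F_ST — the minimum required ratio — rather than at
a measured ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from cultscope.cost_benefit import SelectionRegime, classify_selection_regime
from cultscope.fst_core import GroupFrequencies
from cultscope.io_survey import KeyMismatchError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PracticeScope:
    """Joined per-practice record: differentiation, threshold, economics."""

    practice_id: str
    fst: float
    fst_corrected: float | None
    mls_threshold: float
    regime: SelectionRegime
    mean_net_private_cost: float
    mean_public_benefit: float
    permutation_p: float | None = None
    freqs: GroupFrequencies | None = None


def mls_threshold(fst: float) -> float:
    """Minimum group-benefit-to-individual-cost ratio: ``(1 - fst) / fst``.

    ``fst = 0`` maps to ``inf``; an undefined (NaN) fst propagates to a
    NaN threshold rather than being coerced.
    """
    if isinstance(fst, float) and math.isnan(fst):
        return float("nan")
    if not 0.0 <= fst <= 1.0:
        raise ValueError(f"fst {fst!r} outside [0, 1]")
    if fst == 0.0:
        return float("inf")
    return (1.0 - fst) / fst


def boundary_curve(fst_grid) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the boundary condition on a strictly increasing grid in (0, 1]."""
    grid = np.asarray(fst_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("grid must be a non-empty 1-d sequence")
    if (grid <= 0).any() or (grid > 1).any():
        raise ValueError("grid values must lie in (0, 1]")
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing")
    return grid, (1.0 - grid) / grid


def scope_table(
    fsts,
    econs,
    threshold_from: str = "naive",
) -> list[PracticeScope]:
    """Join F_ST results with practice economics into scope records.

    ``threshold_from`` selects which estimate feeds the threshold:
    ``"naive"`` (default) or ``"corrected"`` (requires the corrected
    estimate on every result).  Keys must match exactly.
    """
    fst_by_key = {r.practice_id: r for r in fsts}
    econ_by_key = {e.practice_id: e for e in econs}
    missing = sorted(set(fst_by_key) - set(econ_by_key))
    extra = sorted(set(econ_by_key) - set(fst_by_key))
    if missing or extra:
        raise KeyMismatchError(
            f"practice keys differ; missing economics for {missing}, "
            f"missing fst for {extra}"
        )

    rows: list[PracticeScope] = []
    for r in fsts:
        e = econ_by_key[r.practice_id]
        if threshold_from == "corrected":
            if r.fst_corrected is None and r.defined:
                raise ValueError(
                    f"practice {r.practice_id!r} has no corrected estimate"
                )
            basis = r.fst_corrected if r.defined else float("nan")
        elif threshold_from == "naive":
            basis = r.fst
        else:
            raise ValueError(f"unknown threshold_from {threshold_from!r}")
        rows.append(
            PracticeScope(
                practice_id=r.practice_id,
                fst=r.fst,
                fst_corrected=r.fst_corrected,
                mls_threshold=mls_threshold(basis),
                regime=classify_selection_regime(e),
                mean_net_private_cost=e.mean_net_private_cost,
                mean_public_benefit=e.mean_public_benefit,
                permutation_p=r.permutation_p,
                freqs=r.freqs,
            )
        )
    return rows


# ---------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------

#: default grid for drawing the boundary curve
DEFAULT_CURVE_GRID = np.linspace(0.02, 1.0, 200)


def render_scope_figure(scopes, out_path, fst_grid=None) -> None:
    """Scatter of (F_ST, minimum required benefit/cost) over the boundary.

    Practices sit on the curve by construction (Likert means cannot form
    measured ratios); the feasible region above the curve is shaded.
    Practices with F_ST = 0 (infinite threshold) are unplottable and are
    omitted with a logged notice.
    """
    import matplotlib.pyplot as plt

    points = [
        (s.fst, s.mls_threshold)
        for s in scopes
        if not math.isnan(s.fst) and math.isfinite(s.mls_threshold)
    ]
    skipped = [
        s.practice_id
        for s in scopes
        if math.isnan(s.fst) or not math.isfinite(s.mls_threshold)
    ]
    if skipped:
        logger.warning(
            "omitting %d practice(s) with undefined or infinite threshold "
            "from the scope figure: %s",
            len(skipped),
            skipped,
        )
    if not points:
        raise ValueError("no practice with a defined, finite F_ST to plot")

    grid, thresholds = boundary_curve(
        DEFAULT_CURVE_GRID if fst_grid is None else fst_grid
    )
    xs, ys = zip(*points)
    top = max(max(thresholds), max(ys)) * 2

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.fill_between(grid, thresholds, top, color="0.85", label="spread feasible")
    ax.plot(grid, thresholds, color="black", lw=1.5, label="(1 - F$_{ST}$)/F$_{ST}$")
    ax.scatter(xs, ys, facecolors="none", edgecolors="C0", zorder=3, label="practices")
    ax.set_yscale("log")
    ax.set_xlim(0, 1.0)
    floor = min(min(ys), min(thresholds)) * 0.5
    ax.set_ylim(max(floor, 1e-3), top)  # log axis: keep the floor positive
    ax.set_xlabel("cultural F$_{ST}$")
    ax.set_ylabel("minimum group benefit / individual cost")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


#: marker area (points^2) corresponding to F_ST = 1, and the floor used
#: so that F_ST = 0 practices remain visible
_MARKER_SCALE = 600.0
_MARKER_FLOOR = 10.0


def render_costbenefit_figure(scopes, out_path) -> None:
    """Public benefit vs net private cost, marker area proportional to F_ST.

    The vertical line at zero net cost splits the plane: the shaded left
    half (net cost <= 0) holds practices individual selection can spread;
    the right half holds cooperative dilemmas that require group
    selection.  Marker areas scale linearly with F_ST, with a small floor
    so F_ST = 0 stays visible.
    """
    import matplotlib.pyplot as plt

    rows = [s for s in scopes if not math.isnan(s.mean_net_private_cost)]
    if not rows:
        raise ValueError("no practice with defined economics to plot")
    x = np.array([s.mean_net_private_cost for s in rows])
    y = np.array([s.mean_public_benefit for s in rows])
    f = np.array([0.0 if math.isnan(s.fst) else s.fst for s in rows])
    sizes = np.maximum(_MARKER_SCALE * f, _MARKER_FLOOR)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    xlim = (min(-6.0, x.min() - 0.5), max(6.0, x.max() + 0.5))
    ax.axvspan(xlim[0], 0.0, color="0.88", zorder=0)
    ax.axvline(0.0, color="black", lw=1)
    ax.scatter(x, y, s=sizes, facecolors="none", edgecolors="C0", zorder=3)
    ax.set_xlim(*xlim)
    ax.set_ylim(1.0, 7.2)
    ax.set_xlabel("mean net private cost (Likert cost - private benefit)")
    ax.set_ylabel("mean public environmental benefit (1-7)")
    ax.annotate("individual selection\npossible", xy=(0.04, 0.95),
                xycoords="axes fraction", va="top", fontsize=8)
    ax.annotate("group selection\nrequired", xy=(0.96, 0.95),
                xycoords="axes fraction", va="top", ha="right", fontsize=8)
    ax.set_title("marker area $\\propto$ F$_{ST}$ (floor for F$_{ST}$=0)", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
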
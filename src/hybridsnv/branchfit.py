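"""Scatter construction, robust LOWESS reference line and branch distances.

A test hybridization is compared against a pure wild-type reference by
plotting per-probe intensities I_test versus I_ref.  Probes unaffected by the
mutant fall on a smooth monotone curve (the *reference line*, the identity
diagonal up to device effects), probes matching the mutant's position and
base are elevated (the *mutation branch*), and probes varying at the same
position with another base sit in between (*side branches*).

Everything is fit in natural-log space of both axes, so the vertical distance
of a probe to the reference line IS the log-ratio statistic

    rho = ln(I_test / I_ref-line)

and any common optical gain applied to both channels cancels exactly.  The
branch distance of a hypothesis is the median distance over its mutation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .probeset import (
    HybridSNVError,
    MutationHypothesis,
    Probeset,
    probes_for_hypothesis,
)
from .simulate import IntensityTable


class InsufficientDataError(HybridSNVError):
    pass


@dataclass
class ScatterData:
    """Paired reference/test intensities per probe.

    ``data`` is indexed by probe_id with columns i_ref, i_test, retained,
    log_ref, log_test (logs only defined for retained probes).  A probe is
    retained when it clears the background threshold in both channels.
    """

    data: pd.DataFrame
    background_threshold: float
    n_dropped: int

    @property
    def retained(self) -> pd.DataFrame:
        return self.data[self.data["retained"]]

    def __len__(self) -> int:
        return len(self.data)


def build_scatter(
    reference: IntensityTable,
    test: IntensityTable,
    background_threshold: float | None = None,
) -> ScatterData:
    """Inner-join the two channels on probe_id and apply the background filter.

    With an explicit ``background_threshold`` a probe is retained when both
    intensities are at or above it (and strictly positive); otherwise the
    tables' own below_background flags decide.
    """
    ref = reference.data.set_index("probe_id")
    tst = test.data.set_index("probe_id")
    shared = ref.index.intersection(tst.index)
    if shared.empty:
        raise HybridSNVError("reference and test tables share no probe_id")
    frame = pd.DataFrame(
        {
            "i_ref": ref.loc[shared, "intensity"],
            "i_test": tst.loc[shared, "intensity"],
        }
    )
    if background_threshold is not None:
        thr = float(background_threshold)
        keep = (frame["i_ref"] >= thr) & (frame["i_test"] >= thr)
    else:
        thr = float("nan")
        keep = ~(
            ref.loc[shared, "below_background"] | tst.loc[shared, "below_background"]
        )
    keep &= (frame["i_ref"] > 0) & (frame["i_test"] > 0)
    frame["retained"] = keep
    frame["log_ref"] = np.where(keep, np.log(frame["i_ref"].where(keep, 1.0)), np.nan)
    frame["log_test"] = np.where(keep, np.log(frame["i_test"].where(keep, 1.0)), np.nan)
    return ScatterData(
        data=frame,
        background_threshold=thr,
        n_dropped=int((~keep).sum()),
    )


@dataclass
class ReferenceLine:
    """Monotone smoothed curve log I_ref -> expected log I_test.

    Evaluated by linear interpolation between the fitted knots; outside the
    fitted range the nearest knot value is used (constant extrapolation).
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    n_robust_iter: int

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.interp(x, self.x, self.y)


def fit_reference_line(
    scatter: ScatterData, span: float = 0.5, n_robust_iter: int = 3
) -> ReferenceLine:
    """Robust LOWESS of log I_test on log I_ref, followed by an isotonic pass.

    The robustifying iterations (bisquare reweighting) let the fit track the
    majority reference branch even when elevated mutation/side branches are
    present; the isotonic pass enforces the physically required monotone
    non-decreasing shape.
    """
    pts = scatter.retained
    if len(pts) < 10:
        raise InsufficientDataError(
            f"only {len(pts)} probes above background; need >= 10 to fit a reference line"
        )
    x = pts["log_ref"].to_numpy()
    y = pts["log_test"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fitted = sm_lowess(y, x, frac=span, it=n_robust_iter, return_sorted=True)
    if not np.all(np.isfinite(fitted)):
        # Degenerate robustness scale (e.g. exactly collinear majority makes the
        # median absolute residual zero); fall back to the unweighted pass.
        fitted = sm_lowess(y, x, frac=span, it=0, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate abscissae so interpolation is well defined
    xs_unique, inverse = np.unique(xs, return_inverse=True)
    ys_unique = np.bincount(inverse, weights=ys) / np.bincount(inverse)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    ys_monotone = iso.fit_transform(xs_unique, ys_unique)
    return ReferenceLine(x=xs_unique, y=ys_monotone, span=span, n_robust_iter=n_robust_iter)


@dataclass
class BranchResult:
    """Per-probe vertical distances and the branch statistic for one hypothesis.

    ``distances`` is indexed by probe_id with columns distance and branch
    (one of reference/mutation/side).  ``rho`` is the median distance over the
    retained mutation set; NaN (with ``valid=False``) when the mutation set
    lost all probes to the background filter.
    """

    hypothesis: MutationHypothesis
    distances: pd.DataFrame
    rho: float
    n_mutation: int
    n_side: int
    n_reference: int
    valid: bool = True

    def pool(self, branch: str) -> np.ndarray:
        return self.distances.loc[
            self.distances["branch"] == branch, "distance"
        ].to_numpy()


def branch_distances(
    scatter: ScatterData,
    line: ReferenceLine,
    probeset: Probeset,
    hypothesis: MutationHypothesis,
) -> BranchResult:
    """Distances of all retained probes to the reference line, labelled by branch.

    The mutation set and side set come from the probeset bookkeeping
    (:func:`probes_for_hypothesis`); every retained probe without a mismatch
    at the hypothesis position belongs to the reference branch.
    """
    mutation_set, side_set = probes_for_hypothesis(probeset, hypothesis)
    mutation_ids = {p.probe_id for p in mutation_set}
    side_ids = {p.probe_id for p in side_set}

    pts = scatter.retained
    distance = pts["log_test"].to_numpy() - np.asarray(line(pts["log_ref"].to_numpy()))
    branch = np.where(
        pts.index.isin(mutation_ids),
        "mutation",
        np.where(pts.index.isin(side_ids), "side", "reference"),
    )
    frame = pd.DataFrame({"distance": distance, "branch": branch}, index=pts.index)

    mut = frame.loc[frame["branch"] == "mutation", "distance"]
    rho = float(mut.median()) if len(mut) else float("nan")
    return BranchResult(
        hypothesis=hypothesis,
        distances=frame,
        rho=rho,
        n_mutation=int((frame["branch"] == "mutation").sum()),
        n_side=int((frame["branch"] == "side").sum()),
        n_reference=int((frame["branch"] == "reference").sum()),
        valid=len(mut) > 0,
    )


def plot_scatter(
    scatter: ScatterData,
    line: ReferenceLine | None = None,
    branches: BranchResult | None = None,
    ax=None,
    title: str | None = None,
):
    """Log-log scatter of test vs reference intensity with the reference line.

    When a :class:`BranchResult` is given, mutation- and side-branch probes
    are highlighted.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = scatter.retained
    if branches is not None:
        lab = branches.distances["branch"].reindex(pts.index).fillna("reference")
        style = {
            "reference": dict(c="0.3", marker="o", s=8, label="reference branch"),
            "side": dict(c="tab:blue", marker="^", s=18, label="side branch"),
            "mutation": dict(c="tab:red", marker="s", s=18, label="mutation branch"),
        }
        for name, kw in style.items():
            sel = lab == name
            ax.scatter(pts.loc[sel, "i_ref"], pts.loc[sel, "i_test"], **kw)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(pts["i_ref"], pts["i_test"], c="0.3", s=8)
    if line is not None:
        xs = np.linspace(pts["log_ref"].min(), pts["log_ref"].max(), 200)
        ax.plot(np.exp(xs), np.exp(line(xs)), "k-", lw=1, label="reference line")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$I_\mathrm{wt}$ (reference)")
    ax.set_ylabel(r"$I_\mathrm{mix}$ (test)")
    if title:
        ax.set_title(title)
    return ax
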
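"""Permutation rarefaction and exponential-decay pangenome extrapolation.

Genomes are added one at a time in many random orders; at every prefix
length the *core curve* records how many clusters are present in all
genomes seen so far, and the *novel curve* how many clusters are observed
for the first time.  Medians over permutations are fitted with the
exponential-decay model

    F(n) = kappa * exp(-n / tau) + omega

whose asymptote ``omega`` extrapolates the minimal core (when fitted to the
core curve) or the per-genome novel-cluster rate (when fitted to the novel
curve); a persistently positive novel-cluster asymptote is the signature of
an open pangenome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TettelinFit:
    """Fitted exponential-decay parameters with diagnostics."""

    kappa: float
    tau: float
    omega: float
    residual_sse: float
    converged: bool

    def predict(self, n: np.ndarray) -> np.ndarray:
        if not np.isfinite(self.tau):
            return np.full_like(np.asarray(n, dtype=float), self.omega)
        return self.kappa * np.exp(-np.asarray(n, dtype=float) / self.tau) + self.omega


def _decay(n: np.ndarray, kappa: float, tau: float, omega: float) -> np.ndarray:
    return kappa * np.exp(-n / tau) + omega


def permute_curves(
    matrix: pd.DataFrame, n_perm: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Core-size and novel-cluster counts along random genome orders.

    Returns a long-format frame with columns ``perm, n, core_size,
    new_clusters``; one row per permutation and prefix length.  The core
    size at ``n = N`` is order-independent (the full intersection), and the
    novel counts of one permutation sum to the number of clusters that
    order ever touches.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    present = (matrix.to_numpy() > 0)
    n_genomes = present.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A]))
    rows = []
    ns = np.arange(1, n_genomes + 1)
    for p in range(n_perm):
        order = rng.permutation(n_genomes)
        path = present[:, order]
        core = np.logical_and.accumulate(path, axis=1).sum(axis=0)
        seen = np.cumsum(path, axis=1) > 0
        first = seen.sum(axis=1)  # cluster seen in the last `first` prefixes
        new = np.zeros(n_genomes, dtype=int)
        touched = first > 0
        first_idx = n_genomes - first[touched]  # 0-based position of first sighting
        np.add.at(new, first_idx, 1)
        for n, c, w in zip(ns, core, new):
            rows.append((p, int(n), int(c), int(w)))
    return pd.DataFrame(rows, columns=["perm", "n", "core_size", "new_clusters"])


def median_curve(curves: pd.DataFrame, column: str = "core_size") -> pd.Series:
    """Median of a rarefaction quantity over permutations, indexed by n."""
    return curves.groupby("n")[column].median()


def fit_tettelin(curve: pd.Series, tau_bounds: tuple[float, float] | None = None) -> TettelinFit:
    """Least-squares fit of ``F(n) = kappa * exp(-n / tau) + omega``.

    Multi-start over a grid of decay constants; ``tau`` is bounded away
    from zero and above by ten times the number of points to keep the
    optimizer off degenerate flat solutions.  A constant curve returns
    ``kappa = 0, tau = nan, omega = mean`` directly.
    """
    n = curve.index.to_numpy(dtype=float)
    y = curve.to_numpy(dtype=float)
    if len(n) < 4:
        raise ValueError("need at least 4 curve points to fit the decay model")
    if np.ptp(y) < 1e-12:
        return TettelinFit(0.0, float("nan"), float(y.mean()), 0.0, True)
    lo, hi = tau_bounds or (1e-6, 10.0 * len(n))
    best = None
    amp0 = y[0] - y[-1]
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    for tau0 in np.geomspace(max(lo, 0.5), hi, 6):
        try:
            popt, _ = curve_fit(
                _decay, n, y,
                p0=[amp0 if abs(amp0) > 1e-9 else 1.0, tau0, y[-1]],
                bounds=([-np.inf, lo, -np.inf], [np.inf, hi, np.inf]),
                max_nfev=2000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((_decay(n, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
        if best[1] / scale < 1e-14:  # essentially exact; further starts are moot
            break
    if best is None:
        return TettelinFit(float("nan"), float("nan"), float("nan"), float("inf"), False)
    (kappa, tau, omega), sse = best
    return TettelinFit(float(kappa), float(tau), float(omega), sse, True)


def fit_curves(curves: pd.DataFrame) -> dict:
    """Fit both median curves and classify openness; tolerant of tiny families.

    The novel-cluster curve is fitted beyond n = 1 (the first proteome
    trivially "discovers" all its clusters).  Families too small for a
    3-parameter fit (< 4 usable points) report ``None`` for that fit and an
    ``"undetermined"`` pangenome.
    """
    import dataclasses

    core_med = median_curve(curves, "core_size")
    new_med = median_curve(curves, "new_clusters")
    new_trim = new_med.iloc[1:] if len(new_med) > 4 else new_med
    core_fit = fit_tettelin(core_med) if len(core_med) >= 4 else None
    new_fit = fit_tettelin(new_trim) if len(new_trim) >= 4 else None
    return {
        "core": dataclasses.asdict(core_fit) if core_fit else None,
        "new_clusters": dataclasses.asdict(new_fit) if new_fit else None,
        "pangenome": openness(new_fit) if new_fit else "undetermined",
    }


def openness(new_cluster_fit: TettelinFit, tolerance: float = 1.0) -> str:
    """Classify the pangenome as open or closed.

    "Open" when the fitted novel-cluster curve still promises more than
    ``tolerance`` new clusters per added genome in the limit; otherwise
    "closed".
    """
    omega = new_cluster_fit.omega
    return "open" if np.isfinite(omega) and omega > tolerance else "closed"


def plot_rarefaction(curves: pd.DataFrame, path, core_fit: TettelinFit | None = None) -> None:
    """Write a rarefaction figure: per-permutation core curves, the median,
    and (optionally) the fitted decay line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for _, grp in curves.groupby("perm"):
        g = grp.sort_values("n")
        ax.plot(g["n"], g["core_size"], color="0.8", lw=0.5, zorder=1)
    med = median_curve(curves, "core_size")
    ax.plot(med.index, med.to_numpy(), "o-", color="firebrick", label="median core", zorder=2)
    if core_fit is not None and core_fit.converged:
        ns = np.linspace(med.index.min(), med.index.max(), 200)
        ax.plot(ns, core_fit.predict(ns), "--", color="black",
                label=f"fit (Ω = {core_fit.omega:.1f})", zorder=3)
    ax.set_xlabel("proteomes sampled")
    ax.set_ylabel("core clusters")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
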
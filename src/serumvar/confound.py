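"""Monte-Carlo simulation of false discoveries under group imbalance.

Imitates biomarker case-control studies in which disease status has no
effect on any analyte, but the patient and control groups are drawn with
differing compositions of two biological pools (males vs females, or OC
users vs cycling females).  Any analyte with a two-sided t-test p-value
below alpha is a false discovery; the simulation sweeps all composition
pairs on a grid and records the average false-discovery percentage with its
Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import stage_rng


@dataclass
class ImbalanceGrid:
    """Composition-pair sweep of average false-discovery percentages."""

    axis_compositions: np.ndarray        # shared control/patient axis
    mean_fd_percent: pd.DataFrame        # control comp x patient comp, %
    mc_se: pd.DataFrame                  # Monte-Carlo SE of the mean, %
    n_reps: int
    group_size: int
    alpha: float
    pool_labels: tuple[str, str]

    def __post_init__(self):
        assert (self.mean_fd_percent.to_numpy() >= 0).all()
        assert (self.mean_fd_percent.to_numpy() <= 100).all()
        assert (self.mc_se.to_numpy() >= 0).all()


def false_discovery_fraction(group_a: np.ndarray, group_b: np.ndarray,
                             alpha: float = 0.05,
                             equal_var: bool = False) -> float:
    """Fraction of analytes separating two groups at ``p < alpha``.

    Runs a two-sided t-test per analyte column (Welch by default); analytes
    with zero variance in both groups count as non-discoveries.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with matching analyte counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue)
    p = np.where(np.isfinite(p), p, 1.0)  # zero variance in both groups
    return float((p < alpha).mean())


def _fd_fractions_vectorized(pool_a: np.ndarray, pool_b: np.ndarray,
                             n_a1: int, n_a2: int, group_size: int,
                             n_reps: int, alpha: float,
                             rng: np.random.Generator) -> np.ndarray:
    """False-discovery fraction for each of ``n_reps`` simulated studies.

    Group 1 takes ``n_a1`` samples from pool A and the rest from pool B
    (group 2 analogously with ``n_a2``), drawn with replacement.  The Welch
    t-tests over all reps and analytes are evaluated in one vectorized pass.
    """
    def draw(n_from_a):
        parts = []
        if n_from_a:
            idx = rng.integers(0, pool_a.shape[0], size=(n_reps, n_from_a))
            parts.append(pool_a[idx])
        if group_size - n_from_a:
            idx = rng.integers(0, pool_b.shape[0],
                               size=(n_reps, group_size - n_from_a))
            parts.append(pool_b[idx])
        return parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)

    g1 = draw(n_a1)            # reps x group_size x analytes
    g2 = draw(n_a2)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    n = group_size
    se2 = v1 / n + v2 / n
    both_const = se2 == 0
    se2 = np.where(both_const, 1.0, se2)
    t = (m1 - m2) / np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / (
            (v1 / n) ** 2 / (n - 1) + (v2 / n) ** 2 / (n - 1)
        )
    df = np.where(np.isfinite(df), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(both_const, 1.0, p)
    return (p < alpha).mean(axis=1)


def simulate_imbalance(pool_a: np.ndarray | pd.DataFrame,
                       pool_b: np.ndarray | pd.DataFrame,
                       group_size: int = 50, step: float = 0.1,
                       n_reps: int = 1000, alpha: float = 0.05,
                       seed: int = 0,
                       pool_labels: tuple[str, str] = ("pool_a", "pool_b"),
                       ) -> ImbalanceGrid:
    """Sweep control/patient composition pairs and record mean FD%.

    For each pair (control composition c, patient composition p) on the
    0..1 grid with the given step, ``round(c * group_size)`` control samples
    come from pool A and the rest from pool B (patients analogously with p),
    drawn with replacement; the per-analyte Welch t-test false-discovery
    fraction is averaged over ``n_reps`` studies.  Per-cell child seeds make
    every cell reproducible in isolation.
    """
    pool_a = np.asarray(pool_a, dtype=float)
    pool_b = np.asarray(pool_b, dtype=float)
    if pool_a.size == 0 or pool_b.size == 0:
        raise ValueError("both pools must be non-empty")
    if pool_a.shape[1] != pool_b.shape[1]:
        raise ValueError("pools must share the analyte axis")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1.0")
    comps = np.round(np.arange(n_steps + 1) * step, 10)
    counts = comps * group_size
    if np.any(np.abs(counts - np.round(counts)) > 1e-9):
        raise ValueError(
            f"group_size={group_size} and step={step} give non-integer "
            "per-pool counts; choose a compatible pair (e.g. 50 and 0.1)"
        )
    counts = np.round(counts).astype(int)

    mean = np.empty((len(comps), len(comps)))
    se = np.empty_like(mean)
    for i, c_ctrl in enumerate(counts):
        for j, c_pat in enumerate(counts):
            rng = stage_rng(seed, "imbalance_cell", i, j)
            fracs = _fd_fractions_vectorized(
                pool_a, pool_b, int(c_ctrl), int(c_pat),
                group_size, n_reps, alpha, rng,
            )
            mean[i, j] = 100.0 * fracs.mean()
            se[i, j] = 100.0 * fracs.std(ddof=1) / np.sqrt(n_reps)
    axis = pd.Index(comps, name="composition")
    return ImbalanceGrid(
        axis_compositions=comps,
        mean_fd_percent=pd.DataFrame(mean, index=axis, columns=axis),
        mc_se=pd.DataFrame(se, index=axis, columns=axis),
        n_reps=n_reps, group_size=group_size, alpha=alpha,
        pool_labels=tuple(pool_labels),
    )


def plot_grid(grid: ImbalanceGrid, path) -> None:
    """Curve plot of mean FD% against control composition, one line per
    patient composition (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    cmap = plt.get_cmap("coolwarm")
    comps = grid.axis_compositions
    for j, pat in enumerate(comps):
        ax.plot(comps, grid.mean_fd_percent.iloc[:, j],
                color=cmap(j / (len(comps) - 1)),
                label=f"{pat:.0%}", linewidth=1.2)
    ax.set_xlabel(f"control group: fraction {grid.pool_labels[0]}")
    ax.set_ylabel("analytes falsely discovered (%)")
    ax.legend(title=f"patient fraction\n{grid.pool_labels[0]}",
              fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_grid(grid: ImbalanceGrid) -> dict:
    """Headline quantities of an imbalance grid.

    ``max_fd_percent`` over all cells, ``balanced_mean_fd_percent`` over the
    equal-composition diagonal, and the mean FD% as a function of the
    absolute composition gap between the two groups.
    """
    m = grid.mean_fd_percent.to_numpy()
    comps = grid.axis_compositions
    k = len(comps)
    gaps: dict[float, list[float]] = {}
    for i in range(k):
        for j in range(k):
            gap = round(abs(comps[i] - comps[j]), 10)
            gaps.setdefault(gap, []).append(m[i, j])
    per_gap = {g: float(np.mean(v)) for g, v in sorted(gaps.items())}
    diag_se = np.sqrt(np.mean(np.diag(grid.mc_se.to_numpy()) ** 2) / k)
    return {
        "max_fd_percent": float(m.max()),
        "balanced_mean_fd_percent": float(np.diag(m).mean()),
        "balanced_mean_mc_se": float(diag_se),
        "per_gap_mean_fd_percent": per_gap,
    }
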
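"""Hyperparameter search: exhaustive grid sweep, Expected-Improvement
acquisition, and a small Gaussian-process Bayesian search over grid cells.

The default grid mirrors the sensitivity study: learning rates
{1e-3, 1e-4, 1e-5} x dropout {0.3, 0.5, 0.7} x batch sizes {32, 64, 128},
27 cells in total.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import norm

__all__ = [
    "TuneGrid",
    "GridResult",
    "grid_search",
    "expected_improvement",
    "bayes_search",
    "sensitivity_report",
]


@dataclass(frozen=True)
class TuneGrid:
    learning_rates: tuple[float, ...] = (1e-3, 1e-4, 1e-5)
    dropouts: tuple[float, ...] = (0.3, 0.5, 0.7)
    batch_sizes: tuple[int, ...] = (32, 64, 128)

    def __post_init__(self) -> None:
        if not (self.learning_rates and self.dropouts and self.batch_sizes):
            raise ValueError("all grid axes must be non-empty")

    def cells(self) -> list[dict]:
        """All combinations, batch-size-major then dropout then learning rate
        (the layout of the sensitivity tables)."""
        return [
            {"batch_size": b, "learning_rate": lr, "dropout": d}
            for b, d, lr in product(self.batch_sizes, self.dropouts, self.learning_rates)
        ]

    def __len__(self) -> int:
        return len(self.learning_rates) * len(self.dropouts) * len(self.batch_sizes)


@dataclass
class GridResult:
    table: list[dict]  # rows: config fields + "score" (None on failure)
    best: dict | None
    failures: list[tuple[dict, str]] = field(default_factory=list)

    def sorted_table(self) -> list[dict]:
        scored = [r for r in self.table if r["score"] is not None]
        return sorted(scored, key=lambda r: -r["score"])


def grid_search(grid: TuneGrid, objective) -> GridResult:
    """Evaluate ``objective(config) -> score`` on every grid cell exactly once.

    A cell whose objective raises is recorded as missing and excluded from
    the argmax; ties resolve to the first cell in axis order.
    """
    table: list[dict] = []
    failures: list[tuple[dict, str]] = []
    best = None
    best_score = -math.inf
    for cfg in grid.cells():
        row = dict(cfg)
        try:
            score = float(objective(cfg))
            row["score"] = score
            if score > best_score:
                best_score, best = score, dict(cfg)
        except Exception as exc:  # noqa: BLE001 - cell failures must not kill the sweep
            row["score"] = None
            failures.append((dict(cfg), str(exc)))
        table.append(row)
    return GridResult(table=table, best=best, failures=failures)


def expected_improvement(mu: float, s: float, f_best: float) -> float:
    """EI = E[max(f(x) - f(x+), 0)] under a Gaussian predictive N(mu, s^2).

    Closed form: with d = mu - f_best and u = d/s,
    ``EI = d * Phi(u) + s * phi(u)`` for s > 0, and ``max(d, 0)`` at s = 0.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    d = mu - f_best
    if s == 0:
        return max(d, 0.0)
    u = d / s
    return float(d * norm.cdf(u) + s * norm.pdf(u))


# ---------------------------------------------------------------------------
# Gaussian-process surrogate over grid cells
# ---------------------------------------------------------------------------


def _encode(cells: list[dict]) -> np.ndarray:
    """Standardized log-scale coordinates for (lr, dropout, batch)."""
    X = np.array(
        [[math.log10(c["learning_rate"]), c["dropout"], math.log2(c["batch_size"])] for c in cells]
    )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _gp_posterior(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, noise: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Squared-exponential kernel, unit signal variance, length-scale 1."""

    def kernel(A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=-1)
        return np.exp(-0.5 * d2)

    K = kernel(X_train, X_train) + noise * np.eye(len(X_train))
    Ks = kernel(X_train, X_test)
    Kss = np.ones(len(X_test))  # diagonal of k(x*, x*)
    L = np.linalg.cholesky(K)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y_train - y_train.mean()))
    mu = Ks.T @ alpha + y_train.mean()
    v = np.linalg.solve(L, Ks)
    var = np.maximum(Kss - (v**2).sum(axis=0), 0.0)
    return mu, np.sqrt(var)


def bayes_search(grid: TuneGrid, objective, n_iter: int, seed: int = 0) -> tuple[dict | None, list[dict]]:
    """EI-guided search over the grid cells with a GP surrogate.

    Starts from one random cell, then repeatedly evaluates the un-evaluated
    cell with maximal EI.  Returns (best config, trace); the trace records
    ``(candidate, ei, score)`` per step.  Stops early when cells run out.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cells = grid.cells()
    coords = _encode(cells)
    rng = np.random.default_rng(seed)
    evaluated: list[int] = []
    scores: list[float] = []
    trace: list[dict] = []

    first = int(rng.integers(len(cells)))
    for step in range(min(n_iter, len(cells))):
        if step == 0:
            idx, ei = first, math.nan
        else:
            remaining = [i for i in range(len(cells)) if i not in evaluated]
            mu, s = _gp_posterior(coords[evaluated], np.array(scores), coords[remaining])
            f_best = max(scores)
            eis = [expected_improvement(m, sd, f_best) for m, sd in zip(mu, s)]
            j = int(np.argmax(eis))
            idx, ei = remaining[j], eis[j]
        score = float(objective(cells[idx]))
        evaluated.append(idx)
        scores.append(score)
        trace.append({"candidate": dict(cells[idx]), "ei": ei, "score": score})
    if not scores:
        return None, trace
    best = dict(cells[evaluated[int(np.argmax(scores))]])
    return best, trace


# ---------------------------------------------------------------------------
# sensitivity views
# ---------------------------------------------------------------------------


def sensitivity_report(table: list[dict], out_dir=None, plots: bool = False) -> dict:
    """Aggregate a grid-search table into the three standard views.

    * ``by_dropout`` — accuracy vs dropout, one line per learning rate
      (mean over batch sizes)
    * ``heatmap``    — accuracy over (dropout x batch size), mean over
      learning rates (declared aggregation rule)
    * ``by_batch``   — accuracy vs batch size per learning rate
      (mean over dropouts)
    """
    rows = [r for r in table if r.get("score") is not None]
    if not rows:
        raise ValueError("empty table")

    def mean_over(keys: tuple[str, ...]) -> dict[tuple, float]:
        acc: dict[tuple, list[float]] = {}
        for r in rows:
            key = tuple(r[k] for k in keys)
            acc.setdefault(key, []).append(r["score"])
        return {k: float(np.mean(v)) for k, v in acc.items()}

    views = {
        "by_dropout": [
            {"learning_rate": lr, "dropout": d, "score": s}
            for (lr, d), s in sorted(mean_over(("learning_rate", "dropout")).items())
        ],
        "heatmap": [
            {"dropout": d, "batch_size": b, "score": s}
            for (d, b), s in sorted(mean_over(("dropout", "batch_size")).items())
        ],
        "by_batch": [
            {"learning_rate": lr, "batch_size": b, "score": s}
            for (lr, b), s in sorted(mean_over(("learning_rate", "batch_size")).items())
        ],
    }
    if out_dir is not None:
        import pathlib

        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, view in views.items():
            with open(out_dir / f"{name}.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(view[0]))
                writer.writeheader()
                writer.writerows(view)
        if plots:
            _plot_views(views, out_dir)
    return views


def _plot_views(views: dict, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    lrs = sorted({r["learning_rate"] for r in views["by_dropout"]})
    for lr in lrs:
        pts = sorted(
            (r["dropout"], r["score"]) for r in views["by_dropout"] if r["learning_rate"] == lr
        )
        ax.plot(*zip(*pts), marker="o", label=f"lr={lr:g}")
    ax.set_xlabel("dropout rate")
    ax.set_ylabel("accuracy")
    ax.legend()
    fig.savefig(out_dir / "by_dropout.png", dpi=120)
    plt.close(fig)

    drops = sorted({r["dropout"] for r in views["heatmap"]})
    batches = sorted({r["batch_size"] for r in views["heatmap"]})
    grid = np.zeros((len(drops), len(batches)))
    for r in views["heatmap"]:
        grid[drops.index(r["dropout"]), batches.index(r["batch_size"])] = r["score"]
    fig, ax = plt.subplots()
    im = ax.imshow(grid, cmap="viridis")
    ax.set_xticks(range(len(batches)), [str(b) for b in batches])
    ax.set_yticks(range(len(drops)), [str(d) for d in drops])
    ax.set_xlabel("batch size")
    ax.set_ylabel("dropout rate")
    fig.colorbar(im)
    fig.savefig(out_dir / "heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    width = 0.8 / len(lrs)
    for i, lr in enumerate(lrs):
        pts = sorted(
            (r["batch_size"], r["score"]) for r in views["by_batch"] if r["learning_rate"] == lr
        )
        xs = np.arange(len(pts)) + i * width
        ax.bar(xs, [p[1] for p in pts], width=width, label=f"lr={lr:g}")
    ax.set_xticks(np.arange(len(batches)) + 0.4 - width / 2, [str(b) for b in batches])
    ax.set_xlabel("batch size")
    ax.set_ylabel("accuracy")
    ax.legend()
    fig.savefig(out_dir / "by_batch.png", dpi=120)
    plt.close(fig)
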
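"""Data IO and population summary statistics.

Two summary conventions are reported side by side, matching how results
from a hierarchical fit are usually presented:

* *hierarchical* statistics — mean, sd and CV of the lognormal population
  distribution evaluated at the posterior means of its (mu, sigma); they
  describe the inferred population law itself;
* *pooled* statistics — sample mean, sd and CV of the per-cell posterior
  means; they describe the collection of individual estimates and are the
  only convention available for a standard (non-hierarchical) fit.

Because all groups share one copy-number distribution, ratios of group
means are comparable between constructs even though absolute per-copy
rates are only identified up to the common copy-number scale.

File formats are deliberately plain: comma-separated UTF-8 CSV with a
header and '.' decimal; configs and summaries as JSON/YAML.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import CellTimeSeries
from .mcmc import ChainResult, McmcConfig, PARAM_NAMES

__all__ = [
    "PopulationSummary",
    "read_timeseries",
    "write_timeseries",
    "lognormal_moments",
    "summarize_population",
    "construct_ratio",
    "sorted_posterior_matrix",
    "save_chain",
    "load_chain",
]

_COLUMNS = ["cell_id", "group", "time", "signal"]


def read_timeseries(path) -> list[CellTimeSeries]:
    """Read a long-format CSV (cell_id, group, time, signal) into cells.

    Rows are grouped by cell and sorted by time; duplicate times within a
    cell and non-numeric fields raise informative errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; header must "
                         f"contain {_COLUMNS}")
    for col in ("time", "signal"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]
            raise ValueError(f"{path}: non-numeric {col!r} values at lines {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[["time", "signal"]].isna().any().any():
        raise ValueError(f"{path}: missing time/signal values")
    out = []
    for (cid, grp), sub in df.groupby(["cell_id", "group"], sort=True):
        sub = sub.sort_values("time")
        times = sub["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise ValueError(f"{path}: duplicated time for cell {cid!r}")
        out.append(CellTimeSeries(cell_id=str(cid), group=str(grp),
                                  times=times,
                                  signals=sub["signal"].to_numpy(dtype=float)))
    return out


def write_timeseries(dataset: list[CellTimeSeries], path) -> None:
    """Write cells to long-format CSV (round-trips through read_timeseries)."""
    rows = [pd.DataFrame({"cell_id": ts.cell_id, "group": ts.group,
                          "time": ts.times, "signal": ts.signals})
            for ts in dataset]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def lognormal_moments(mu: float, sigma: float) -> tuple[float, float, float]:
    """(mean, sd, cv) of a lognormal from its underlying normal (mu, sigma).

    mean = exp(mu + sigma²/2); cv = sqrt(exp(sigma²) − 1) depends on sigma
    only; sd = mean·cv.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mean = math.exp(mu + 0.5 * sigma * sigma)
    cv = math.sqrt(math.expm1(sigma * sigma))
    return mean, mean * cv, cv


@dataclass
class PopulationSummary:
    """Per-group population statistics of the active transcription rate.

    ``hier`` maps group → (mean, sd, cv) of the fitted population lognormal
    (None for standard-mode chains); ``pooled`` maps group → (mean, sd, cv)
    of the per-cell posterior means.  ``mode`` records which fit produced it.
    """

    hier: dict | None
    pooled: dict
    mode: str
    n_cells: dict

    @property
    def groups(self) -> list:
        return sorted(self.pooled)

    def group_mean(self, group) -> float:
        """Preferred point estimate: hierarchical mean when available."""
        if self.hier is not None:
            return self.hier[group][0]
        return self.pooled[group][0]

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "n_cells": self.n_cells,
             "pooled": {g: list(v) for g, v in self.pooled.items()}}
        d["hier"] = ({g: list(v) for g, v in self.hier.items()}
                     if self.hier is not None else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSummary":
        hier = ({g: tuple(v) for g, v in d["hier"].items()}
                if d.get("hier") else None)
        return cls(hier=hier,
                   pooled={g: tuple(v) for g, v in d["pooled"].items()},
                   mode=d["mode"], n_cells=d["n_cells"])


def summarize_population(chains: ChainResult) -> PopulationSummary:
    """Population summary of the on-rate in both reporting conventions.

    Hierarchical statistics come from ``lognormal_moments`` at the
    posterior means of each group's (mu, sigma); pooled statistics from
    the sample moments of the per-cell posterior-mean on-rates.
    """
    groups = chains.group_labels
    if not groups:
        raise ValueError("chain has no groups")
    cell_means = chains.posterior_mean_cell()
    pooled = {}
    n_cells = {}
    for g in groups:
        vals = cell_means.loc[cell_means["group"] == g, "tau_on"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has no cells")
        m = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        pooled[g] = (m, sd, sd / m)
        n_cells[g] = int(len(vals))
    hier = None
    if chains.config.mode == "hierarchical":
        hm = chains.hyper_mean()
        hier = {g: lognormal_moments(hm[f"mu_tau_on[{g}]"],
                                     hm[f"sigma_tau_on[{g}]"])
                for g in groups}
    return PopulationSummary(hier=hier, pooled=pooled,
                             mode=chains.config.mode, n_cells=n_cells)


def construct_ratio(summary: PopulationSummary, group_x, group_y) -> float:
    """Ratio of group mean on-rates mean(X)/mean(Y).

    Uses hierarchical means when present, pooled means otherwise.  Both
    groups share the copy-number distribution, so the ratio is the
    comparable between-construct quantity.
    """
    for g in (group_x, group_y):
        if g not in summary.pooled:
            raise KeyError(f"group {g!r} not in summary (has {summary.groups})")
    return summary.group_mean(group_x) / summary.group_mean(group_y)


def ratio_posterior(chains: ChainResult, group_x, group_y) -> np.ndarray:
    """Posterior draws of the population-mean ratio mean(X)/mean(Y).

    For hierarchical chains, each kept draw of the hyperparameters maps to
    a lognormal mean per group; the ratio of those means gives the full
    posterior of the between-construct ratio for interval reporting.
    """
    if chains.config.mode != "hierarchical":
        raise ValueError("ratio posterior requires a hierarchical chain")
    names = chains.hyper_names
    out = np.empty(chains.n_kept)
    ix = {n: i for i, n in enumerate(names)}
    for g in (group_x, group_y):
        if f"mu_tau_on[{g}]" not in ix:
            raise KeyError(f"group {g!r} not in chain")
    mu_x = chains.hyper_samples[:, ix[f"mu_tau_on[{group_x}]"]]
    sd_x = chains.hyper_samples[:, ix[f"sigma_tau_on[{group_x}]"]]
    mu_y = chains.hyper_samples[:, ix[f"mu_tau_on[{group_y}]"]]
    sd_y = chains.hyper_samples[:, ix[f"sigma_tau_on[{group_y}]"]]
    out[:] = np.exp(mu_x + 0.5 * sd_x**2 - mu_y - 0.5 * sd_y**2)
    return out


def sorted_posterior_matrix(chains: ChainResult, n_bins: int = 100):
    """Per-cell normalized histograms of on-rate samples, sorted by mean.

    Returns (matrix, bin_edges, cell_order): one row per cell on a common
    grid spanning the pooled 0.5–99.5 percentile range, rows ordered by
    ascending posterior mean — the heat-strip view of the per-cell
    posteriors.
    """
    samples = chains.cell_samples[:, :, PARAM_NAMES.index("tau_on")]
    if samples.shape[1] < 1:
        raise ValueError("need at least one cell")
    lo, hi = np.percentile(samples, [0.5, 99.5])
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    means = samples.mean(axis=0)
    order = np.argsort(means, kind="stable")
    mat = np.empty((samples.shape[1], n_bins))
    for r, j in enumerate(order):
        counts, _ = np.histogram(np.clip(samples[:, j], lo, hi), bins=edges)
        mat[r] = counts / counts.sum()
    return mat, edges, [chains.cell_ids[j] for j in order]


def plot_sorted_posteriors(chains: ChainResult, ax=None, n_bins: int = 100):
    """Render the sorted per-cell posterior matrix as a heat-strip image."""
    import matplotlib.pyplot as plt

    mat, edges, order = sorted_posterior_matrix(chains, n_bins)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.2 * len(order) + 1))
    ax.imshow(mat, aspect="auto", origin="lower", cmap="viridis",
              extent=[edges[0], edges[-1], 0, len(order)])
    ax.set_xlabel("relative per-copy on-rate")
    ax.set_ylabel("cell (sorted by posterior mean)")
    return ax


# ---------------------------------------------------------------------------
# chain persistence: delimited-text sample tables + JSON metadata sidecar

def save_chain(chains: ChainResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chains.cell_frame().to_csv(out / "cell_samples.csv", index=False)
    chains.hyper_frame().to_csv(out / "hyper_samples.csv", index=False)
    ll = pd.DataFrame(chains.loglik_trace, columns=chains.cell_ids)
    ll.insert(0, "draw", np.arange(chains.n_kept))
    ll.to_csv(out / "loglik_trace.csv", index=False)
    cfg = asdict(chains.config)
    meta = {
        "config": cfg, "fixed": chains.fixed, "seed": chains.seed,
        "acceptance": chains.acceptance, "group_labels": chains.group_labels,
        "cell_ids": chains.cell_ids, "cell_groups": chains.cell_groups,
        "hyper_names": chains.hyper_names,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_chain(out_dir) -> ChainResult:
    out = Path(out_dir)
    meta = json.loads((out / "metadata.json").read_text())
    cfg = McmcConfig(**meta["config"])
    cells = pd.read_csv(out / "cell_samples.csv")
    hyper = pd.read_csv(out / "hyper_samples.csv")
    ll = pd.read_csv(out / "loglik_trace.csv")
    cell_ids = meta["cell_ids"]
    n_kept = int(cells["draw"].max()) + 1
    cell_samples = np.empty((n_kept, len(cell_ids), 6))
    for j, cid in enumerate(cell_ids):
        sub = cells[cells["cell_id"] == cid].sort_values("draw")
        cell_samples[:, j, :] = sub[PARAM_NAMES].to_numpy()
    return ChainResult(
        cell_samples=cell_samples,
        hyper_samples=hyper[meta["hyper_names"]].to_numpy(),
        hyper_names=meta["hyper_names"],
        loglik_trace=ll[cell_ids].to_numpy(),
        cell_ids=cell_ids, cell_groups=meta["cell_groups"],
        group_labels=meta["group_labels"], acceptance=meta["acceptance"],
        config=cfg, fixed=meta["fixed"], seed=meta["seed"])
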
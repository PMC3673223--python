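"""Model/Results front door, in the style of statsmodels.

``TranscriptionRateModel`` is built from a long-format table of single-cell
fluorescence onset curves plus the fixed constants (degradation rates and
fluorescence-per-molecule); ``fit()`` runs the MCMC sampler and returns a
``TranscriptionRateResults`` carrying the chains, population summaries,
between-construct ratios with credible intervals, convergence diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .kinetics import CellTimeSeries
from .mcmc import ChainResult, McmcConfig, run_mcmc
from .reporting import (
    PopulationSummary,
    construct_ratio,
    ratio_posterior,
    read_timeseries,
    summarize_population,
    sorted_posterior_matrix,
    plot_sorted_posteriors,
)

__all__ = ["TranscriptionRateModel", "TranscriptionRateResults"]


class TranscriptionRateModel:
    """Hierarchical (or standard) model of a population of onset curves.

    Parameters
    ----------
    dataset : list of CellTimeSeries
        One entry per cell, each with its construct group label.
    delta_M, delta_P : float
        Known mRNA/protein degradation rates (time⁻¹), fixed during
        inference (a single off→on switch carries little information on
        degradation, so these must be supplied).
    kappa : float
        Known fluorescence per protein molecule.
    mode : {"hierarchical", "standard"}
        Full two-layer model, or the non-hierarchical baseline with wide
        fixed priors.
    **config
        Any further :class:`~hiertx.mcmc.McmcConfig` field.

    Examples
    --------
    >>> model = TranscriptionRateModel.from_dataframe(df, delta_M=0.2,
    ...                                               delta_P=0.05, kappa=1.0)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, dataset, delta_M: float, delta_P: float, kappa: float,
                 mode: str = "hierarchical", **config):
        if not dataset:
            raise ValueError("dataset is empty")
        for ts in dataset:
            if not isinstance(ts, CellTimeSeries):
                raise TypeError("dataset entries must be CellTimeSeries")
        ids = [ts.cell_id for ts in dataset]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell ids in dataset")
        self.dataset = list(dataset)
        self.fixed = {"delta_M": float(delta_M), "delta_P": float(delta_P),
                      "kappa": float(kappa)}
        self.config = McmcConfig(mode=mode, **config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TranscriptionRateModel":
        """Build from a long-format frame with columns cell_id/group/time/signal."""
        dataset = []
        for (cid, grp), sub in df.groupby(["cell_id", "group"], sort=True):
            sub = sub.sort_values("time")
            dataset.append(CellTimeSeries(
                cell_id=str(cid), group=str(grp),
                times=sub["time"].to_numpy(dtype=float),
                signals=sub["signal"].to_numpy(dtype=float)))
        return cls(dataset, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TranscriptionRateModel":
        return cls(read_timeseries(path), **kwargs)

    @property
    def groups(self) -> list:
        return sorted({ts.group for ts in self.dataset})

    def fit(self, seed: int | None = None, **overrides) -> "TranscriptionRateResults":
        """Run the sampler and return the results object.

        ``seed`` and any McmcConfig field can be overridden per fit without
        mutating the model's configuration.
        """
        cfg = self.config
        if seed is not None:
            overrides = {**overrides, "seed": int(seed)}
        if overrides:
            cfg = replace(cfg, **overrides)
        chain = run_mcmc(self.dataset, self.fixed, cfg)
        return TranscriptionRateResults(self, chain)


class TranscriptionRateResults:
    """Fit results: chains, summaries, ratios, diagnostics."""

    def __init__(self, model: TranscriptionRateModel, chain: ChainResult):
        self.model = model
        self.chain = chain
        self._summary: PopulationSummary | None = None

    @property
    def population_summary(self) -> PopulationSummary:
        if self._summary is None:
            self._summary = summarize_population(self.chain)
        return self._summary

    @property
    def groups(self) -> list:
        return self.chain.group_labels

    def construct_ratio(self, group_x, group_y) -> float:
        """Point estimate of the between-construct mean on-rate ratio."""
        return construct_ratio(self.population_summary, group_x, group_y)

    def ratio_interval(self, group_x, group_y, prob: float = 0.95):
        """Equal-tailed posterior credible interval for the ratio."""
        draws = ratio_posterior(self.chain, group_x, group_y)
        a = 0.5 * (1.0 - prob)
        lo, hi = np.quantile(draws, [a, 1.0 - a])
        return float(lo), float(hi)

    def posterior_mean_cell(self) -> pd.DataFrame:
        return self.chain.posterior_mean_cell()

    def credible_interval_cell(self, param: str = "tau_on", prob: float = 0.95,
                               combined_with_copy: bool = False) -> pd.DataFrame:
        """Per-cell credible intervals, optionally for the product c·tau_on.

        The product is the quantity the data identify for a single cell;
        individual c and tau_on intervals are wide by construction.
        """
        from .mcmc import PARAM_NAMES

        if combined_with_copy:
            samples = (self.chain.cell_samples[:, :, PARAM_NAMES.index("copy_number")]
                       * self.chain.cell_samples[:, :, PARAM_NAMES.index(param)])
        else:
            samples = self.chain.cell_samples[:, :, PARAM_NAMES.index(param)]
        a = 0.5 * (1.0 - prob)
        lo, hi = np.quantile(samples, [a, 1.0 - a], axis=0)
        return pd.DataFrame({"cell_id": self.chain.cell_ids,
                             "group": self.chain.cell_groups,
                             "mean": samples.mean(axis=0), "lo": lo, "hi": hi})

    def diagnostics(self) -> pd.DataFrame:
        """Split-R̂ and effective sample size for the population parameters.

        Reported for monitoring only, never used as a stopping rule.  In
        standard mode the population layer is constant, so diagnostics are
        computed on the per-cell on-rates instead.
        """
        import arviz as az

        if self.chain.config.mode == "hierarchical":
            names = self.chain.hyper_names
            data = {n: self.chain.hyper_samples[None, :, i]
                    for i, n in enumerate(names)}
        else:
            from .mcmc import PARAM_NAMES
            j = PARAM_NAMES.index("tau_on")
            data = {f"tau_on[{cid}]": self.chain.cell_samples[None, :, k, j]
                    for k, cid in enumerate(self.chain.cell_ids)}
        idata = az.from_dict(posterior=data)
        ess = az.ess(idata)
        rhat = az.rhat(idata)
        rows = [{"parameter": n,
                 "ess": float(ess[n].values),
                 "rhat": float(rhat[n].values)} for n in data]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (population table, ratios, acceptance)."""
        ps = self.population_summary
        ch = self.chain
        lines = []
        lines.append("      Transcription-rate population model")
        lines.append("=" * 62)
        lines.append(f"mode: {ch.config.mode:<14} cells: {len(ch.cell_ids):<5} "
                     f"kept draws: {ch.n_kept}")
        lines.append(f"iterations: {ch.config.n_iterations}  "
                     f"burn-in: {ch.config.burn_in}  thin: {ch.config.thin}  "
                     f"seed: {ch.seed}")
        lines.append("-" * 62)
        lines.append(f"{'group':<8}{'n':>4}{'hier mean':>11}{'hier sd':>9}"
                     f"{'hier cv':>9}{'pool mean':>11}{'pool cv':>9}")
        for g in ps.groups:
            pm, psd, pcv = ps.pooled[g]
            if ps.hier is not None:
                hm, hsd, hcv = ps.hier[g]
                lines.append(f"{g:<8}{ps.n_cells[g]:>4}{hm:>11.3f}{hsd:>9.3f}"
                             f"{hcv:>9.3f}{pm:>11.3f}{pcv:>9.3f}")
            else:
                lines.append(f"{g:<8}{ps.n_cells[g]:>4}{'--':>11}{'--':>9}"
                             f"{'--':>9}{pm:>11.3f}{pcv:>9.3f}")
        lines.append("-" * 62)
        lines.append("between-construct mean on-rate ratios:")
        gs = ps.groups
        for i in range(len(gs)):
            for j in range(i):
                r = self.construct_ratio(gs[i], gs[j])
                if ch.config.mode == "hierarchical":
                    lo, hi = self.ratio_interval(gs[i], gs[j])
                    lines.append(f"  {gs[i]}/{gs[j]}: {r:7.3f}   "
                                 f"95% CI [{lo:.3f}, {hi:.3f}]")
                else:
                    lines.append(f"  {gs[i]}/{gs[j]}: {r:7.3f}")
        lines.append("-" * 62)
        lines.append("acceptance rates:")
        for k, v in ch.acceptance.items():
            if k.startswith("cells"):
                lines.append(f"  {k}: {v:.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    def sorted_posterior_matrix(self, n_bins: int = 100):
        return sorted_posterior_matrix(self.chain, n_bins)

    def plot_posteriors(self, ax=None, n_bins: int = 100):
        return plot_sorted_posteriors(self.chain, ax=ax, n_bins=n_bins)
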
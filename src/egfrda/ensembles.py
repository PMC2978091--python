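"""Comparison and influence analysis of fitted parameter ensembles.

``compare_ensembles`` contrasts the WT and mutant posterior ensembles
parameter by parameter: log2 fold change of the ensemble means, Welch's
unequal-variance t-test on the particle samples (treated as independent
draws -- a known optimistic approximation, flagged in the output), and
Bonferroni adjustment over the number of parameters compared.

``lpi_analysis`` ranks parameters by phenotypic impact (local parameter
influence): each fitted mutant parameter is reset, one at a time, to
its WT value and the data likelihood of the re-simulated model is
compared with the original mutant likelihood on a log10 scale.  A
strongly negative value marks a parameter whose mutant-specific value
is essential for reproducing the mutant data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assimilation import LikelihoodResult, ObservationModel, ParticleEnsemble, make_loglik
from .network import ParameterSet

log = logging.getLogger(__name__)


def compare_ensembles(wt: ParticleEnsemble, mut: ParticleEnsemble,
                      fc_min: float = 2.0, p_max: float = 0.001,
                      parameters=None, resample_seed: int = 0) -> pd.DataFrame:
    """Per-parameter WT-vs-mutant comparison table.

    A parameter is flagged significant when |log2 fold change of the
    ensemble means| >= log2(fc_min) AND the Bonferroni-adjusted Welch
    p-value <= p_max.  Parameters with zero variance in both ensembles
    are untestable and flagged not-significant.  Note: particles are
    correlated samples; the t-test treats them as independent.
    """
    if list(wt.parameter_ids) != list(mut.parameter_ids):
        raise ValueError("ensembles do not share parameter ids")
    wt_s = wt.equal_weight_resample(seed=resample_seed)
    mut_s = mut.equal_weight_resample(seed=resample_seed + 1)
    if parameters is None:
        parameters = [p for p in wt.parameter_ids
                      if wt_s.column(p).std() > 0 or mut_s.column(p).std() > 0]
    m = len(parameters)
    rows = []
    for pid in parameters:
        a, b = wt_s.column(pid), mut_s.column(pid)
        mean_wt, mean_mut = float(a.mean()), float(b.mean())
        lfc = math.log2(mean_mut / mean_wt) if mean_wt > 0 and mean_mut > 0 else math.nan
        if a.std() == 0 and b.std() == 0:
            log.warning("compare_ensembles: %s has zero variance in both "
                        "ensembles; test undefined", pid)
            p = math.nan
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        p_adj = min(1.0, m * p) if not math.isnan(p) else math.nan
        sig = (not math.isnan(lfc) and not math.isnan(p_adj)
               and abs(lfc) >= math.log2(fc_min) and p_adj <= p_max)
        rows.append((pid, mean_wt, mean_mut, lfc, p, p_adj, sig))
    return pd.DataFrame(rows, columns=[
        "parameter", "mean_WT", "mean_mutant", "log2_fold_change",
        "p_value", "p_adjusted", "significant"]).set_index("parameter")


def significant_parameters(comparison: pd.DataFrame, p_max: float = 0.001,
                           adjusted: bool = True) -> list:
    """Parameters passing the p-value cut alone (the LPI candidate set)."""
    col = "p_adjusted" if adjusted else "p_value"
    sel = comparison[comparison[col] <= p_max]
    return list(sel.index)


@dataclass
class LpiResult:
    likelihood_original: float
    table: pd.DataFrame  # per parameter: likelihood_reset, log10_fold_change, failed
    per_protein: dict = field(default_factory=dict)  # parameter -> {protein: log10 fc}
    wt_model_log10_fold_change: float = None

    def ranking(self) -> pd.DataFrame:
        ok = self.table[~self.table["failed"]]
        return ok.reindex(ok["log10_fold_change"].abs()
                          .sort_values(ascending=False).index)


def lpi_analysis(network, mut_best: ParameterSet, wt_values: ParameterSet,
                 target_params, data, obs: ObservationModel,
                 condition="Y992F") -> LpiResult:
    """Local parameter influence: reset each target parameter of the fitted
    mutant model to its WT value and report the log10 fold change of the
    data likelihood (overall = geometric mean over proteins, and per
    protein).  Also evaluates the all-parameters-at-WT model as the
    negative control."""
    loglik = make_loglik(network, data, obs, condition)
    base = loglik(mut_best)
    if not math.isfinite(base.log_overall):
        raise ValueError("mutant model itself fails to simulate")
    rows, per_protein = [], {}
    for pid in target_params:
        reset = mut_best.with_updates({pid: wt_values[pid]})
        res: LikelihoodResult = loglik(reset)
        failed = not math.isfinite(res.log_overall)
        lfc = ((res.log_overall - base.log_overall) / math.log(10)
               if not failed else math.nan)
        if failed:
            log.warning("LPI: simulation failed for reset of %s; excluded", pid)
        else:
            per_protein[pid] = {
                p: (res.log_per_protein[p] - base.log_per_protein[p]) / math.log(10)
                for p in base.log_per_protein}
        rows.append((pid, res.overall, lfc, failed))
    table = pd.DataFrame(rows, columns=[
        "parameter", "likelihood_reset", "log10_fold_change", "failed",
    ]).set_index("parameter")
    wt_all = loglik(ParameterSet(mut_best).with_updates(
        {p: wt_values[p] for p in wt_values}))
    wt_fc = ((wt_all.log_overall - base.log_overall) / math.log(10)
             if math.isfinite(wt_all.log_overall) else math.nan)
    return LpiResult(base.overall, table, per_protein, wt_fc)


def kde_parameter_density(ensemble: ParticleEnsemble, parameter_id: str,
                          grid_size: int = 256):
    """Gaussian KDE of a parameter's posterior on the log10 scale
    (Silverman bandwidth).  Returns (log10 grid, density); the density
    integrates to ~1 over the grid."""
    x = np.log10(ensemble.equal_weight_resample(seed=0).column(parameter_id))
    if np.unique(x).size < 2:
        raise ValueError(f"degenerate density: {parameter_id} has < 2 distinct values")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 4.0 * x.std()
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    return grid, kde(grid)
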
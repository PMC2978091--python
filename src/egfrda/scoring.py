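"""SILAC phospho-time-course tables and functional scoring.

Implements the quantitation conventions of the two-cell-line SILAC
design (wild-type vs Y992F EGFR): anchoring of relative quantitation to
the WT value at 5 min of EGF stimulation, replicate combination,
activation / deviation scores, the EGF-dependence fold-change filter,
and the normalization chain used for model fitting.

The activation score ``A`` of a protein is the ratio of the area under
the mutant time course to the area under the WT time course, both on
the WT-5-min-anchored scale: ``A = AUC(m_Y992F) / AUC(m_WT)`` with
trapezoidal areas over the shared time grid.  ``A > 1`` means the
protein is more phosphorylated in the mutant overall.

The deviation score ``D`` compares the *shapes* of the two time courses
after each is self-normalized to its own 5-min value:
``D = sqrt(mean_i (n_WT(t_i) - n_Y992F(t_i))^2)`` (root-mean-square by
default; a plain summed variant is available).  ``D = 0`` for
proportional profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WT = "WT"
MUTANT = "Y992F"
CONDITIONS = (WT, MUTANT)

#: anchor time (min) and the fallback anchors tried when it is missing
ANCHOR_TIME = 5.0
FALLBACK_ANCHORS = (1.0, 20.0)


class ScoreError(ValueError):
    """A score is undefined for this protein (zero/missing denominator)."""


@dataclass
class TimeCourseTable:
    """protein x condition x time table of non-negative relative
    quantitation values (NaN = missing).

    ``data`` is a DataFrame indexed by (protein, condition) with the time
    points (minutes, increasing) as columns.
    """

    data: pd.DataFrame
    flags: dict = field(default_factory=dict)  # protein -> set of str
    provenance: dict = field(default_factory=dict)  # protein -> experiment ids

    def __post_init__(self):
        times = list(self.data.columns)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")

    # -- accessors ----------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def proteins(self) -> list:
        return sorted({p for p, _ in self.data.index})

    @property
    def conditions(self) -> list:
        return sorted({c for _, c in self.data.index})

    def series(self, protein, condition) -> np.ndarray:
        return self.data.loc[(protein, condition)].to_numpy(dtype=float)

    def has(self, protein, condition=None) -> bool:
        if condition is None:
            return any(p == protein for p, _ in self.data.index)
        return (protein, condition) in self.data.index

    def flag(self, protein, name):
        self.flags.setdefault(protein, set()).add(name)

    def copy(self) -> "TimeCourseTable":
        return TimeCourseTable(
            self.data.copy(), {p: set(f) for p, f in self.flags.items()},
            dict(self.provenance),
        )

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TimeCourseTable":
        """Build from long format (columns: protein_id, condition, time_min,
        value, optional experiment_id)."""
        required = {"protein_id", "condition", "time_min", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        dup = df.duplicated(["protein_id", "condition", "time_min"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate (protein, condition, time) key: "
                f"({row.protein_id}, {row.condition}, {row.time_min})"
            )
        if (df["value"].dropna() < 0).any():
            raise ValueError("negative quantitation value")
        wide = df.pivot(index=["protein_id", "condition"], columns="time_min",
                        values="value")
        wide = wide[sorted(wide.columns)]
        wide.index.names = [None, None]
        wide.columns.name = None
        prov = {}
        if "experiment_id" in df.columns:
            for p, g in df.groupby("protein_id"):
                prov[p] = sorted(set(g["experiment_id"].dropna().astype(str)))
        return cls(wide, provenance=prov)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (p, c), row in self.data.iterrows():
            exp = ";".join(self.provenance.get(p, [])) or "NA"
            for t, v in row.items():
                if not math.isnan(v):
                    rows.append((p, c, float(t), float(v), exp))
        return pd.DataFrame(rows, columns=["protein_id", "condition", "time_min",
                                           "value", "experiment_id"])


def _anchor_value(values: np.ndarray, times: np.ndarray):
    """The anchor value at 5 min, falling back to 1 then 20 min.
    Returns (value, anchor_time) or (None, None)."""
    for t in (ANCHOR_TIME,) + FALLBACK_ANCHORS:
        hit = np.where(times == t)[0]
        if hit.size and not math.isnan(values[hit[0]]) and values[hit[0]] > 0:
            return float(values[hit[0]]), t
    return None, None


def normalize_to_reference(table: TimeCourseTable,
                           reference=(WT, ANCHOR_TIME)) -> TimeCourseTable:
    """Divide every value of a protein by that protein's value in the
    reference (condition, time); idempotent.  A missing 5-min anchor falls
    back to 1 min then 20 min (the protein is flagged); a protein with no
    usable anchor is dropped with a warning."""
    ref_cond, ref_time = reference
    out = table.copy()
    times = out.times
    drop = []
    for protein in out.proteins:
        if not out.has(protein, ref_cond):
            log.warning("normalize: %s has no %s series; dropped", protein, ref_cond)
            drop.append(protein)
            continue
        ref_series = out.series(protein, ref_cond)
        # honor the requested anchor first, then the standard fallbacks
        anchor, used = None, None
        hit = np.where(times == ref_time)[0]
        if hit.size and not math.isnan(ref_series[hit[0]]) and ref_series[hit[0]] > 0:
            anchor, used = float(ref_series[hit[0]]), ref_time
        else:
            anchor, used = _anchor_value(ref_series, times)
        if anchor is None:
            log.warning("normalize: %s has no usable anchor; dropped", protein)
            drop.append(protein)
            continue
        if used != ref_time:
            out.flag(protein, f"anchor_fallback:{used:g}min")
        for cond in out.conditions:
            if out.has(protein, cond):
                out.data.loc[(protein, cond)] = out.series(protein, cond) / anchor
    if drop:
        keep = [i for i in out.data.index if i[0] not in set(drop)]
        out.data = out.data.loc[keep]
    return out


def self_normalize(table: TimeCourseTable, anchor_time=ANCHOR_TIME) -> TimeCourseTable:
    """Normalize every (protein, condition) series to its own anchor value
    (5 min, with the standard fallbacks)."""
    out = table.copy()
    times = out.times
    drop = []
    for (protein, cond) in list(out.data.index):
        series = out.series(protein, cond)
        anchor, used = _anchor_value(series, times)
        if anchor is None:
            log.warning("self-normalize: (%s, %s) has no usable anchor; dropped",
                        protein, cond)
            drop.append((protein, cond))
            continue
        if used != anchor_time:
            out.flag(protein, f"anchor_fallback:{used:g}min")
        out.data.loc[(protein, cond)] = series / anchor
    if drop:
        out.data = out.data.drop(index=drop)
    return out


def combine_replicates(rep1: TimeCourseTable, rep2: TimeCourseTable,
                       wt_anchor: dict) -> TimeCourseTable:
    """Combine duplicate mutant measurements: self-normalize each replicate
    to its 5-min value, average pointwise (pairwise-complete), then scale
    by the per-protein mutant/WT 5-min activation ratio ``wt_anchor``."""
    n1, n2 = self_normalize(rep1), self_normalize(rep2)
    times = rep1.times
    if not np.array_equal(times, rep2.times):
        raise ValueError("replicates must share the time grid")
    rows, index = [], []
    flags = {}
    for key in sorted(set(n1.data.index) | set(n2.data.index)):
        stack = [t.series(*key) for t in (n1, n2) if key in t.data.index]
        mean = np.nanmean(np.vstack(stack), axis=0)
        protein = key[0]
        ratio = wt_anchor.get(protein)
        if ratio is None:
            log.warning("combine: no WT anchor ratio for %s; dropped", protein)
            continue
        rows.append(mean * ratio)
        index.append(key)
        fl = n1.flags.get(protein, set()) | n2.flags.get(protein, set())
        if fl:
            flags[protein] = fl
    data = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index), columns=rep1.data.columns)
    prov = {}
    for p in {k[0] for k in index}:
        prov[p] = sorted(set(rep1.provenance.get(p, [])) | set(rep2.provenance.get(p, [])))
    return TimeCourseTable(data, flags, prov)


def _shared_grid(table, protein):
    """(times, wt values, mutant values) at points where both are present."""
    if not (table.has(protein, WT) and table.has(protein, MUTANT)):
        raise ScoreError(f"{protein}: both conditions required")
    wt = table.series(protein, WT)
    mut = table.series(protein, MUTANT)
    ok = ~(np.isnan(wt) | np.isnan(mut))
    if ok.sum() < 2:
        raise ScoreError(f"{protein}: fewer than 2 shared time points")
    return table.times[ok], wt[ok], mut[ok]


def activation_score(table: TimeCourseTable, protein) -> float:
    """A = AUC(m_Y992F) / AUC(m_WT), trapezoidal, on the WT-5-min scale."""
    t, wt, mut = _shared_grid(table, protein)
    auc_wt = np.trapezoid(wt, t)
    if auc_wt == 0:
        raise ScoreError(f"{protein}: WT AUC is zero, activation score undefined")
    return float(np.trapezoid(mut, t) / auc_wt)


def deviation_score(table: TimeCourseTable, protein, form="rms") -> float:
    """Pattern deviation of the self-normalized profiles.

    ``form='rms'`` (default): sqrt(mean((n_WT - n_Y992F)^2));
    ``form='sum'``: sum |n_WT - n_Y992F|.
    """
    normed = self_normalize(table)
    t, wt, mut = _shared_grid(normed, protein)
    diff = wt - mut
    if form == "rms":
        return float(np.sqrt(np.mean(diff ** 2)))
    if form == "sum":
        return float(np.sum(np.abs(diff)))
    raise ValueError(f"unknown deviation form {form!r}")


def filter_egf_dependent(table: TimeCourseTable, threshold: float = 1.5,
                         mode: str = "maxmin") -> list:
    """Proteins whose time course changes at least ``threshold``-fold in
    either cell line.

    ``mode='maxmin'`` (default): max over time / min over time;
    ``mode='vs_t0'``: max over time of value / value at t=0.
    """
    kept = []
    for protein in table.proteins:
        best = 0.0
        usable = False
        for cond in table.conditions:
            if not table.has(protein, cond):
                continue
            v = table.series(protein, cond)
            v = v[~np.isnan(v)]
            if v.size < 2:
                continue
            usable = True
            if mode == "maxmin":
                if v.min() > 0:
                    best = max(best, v.max() / v.min())
            elif mode == "vs_t0":
                t0 = table.series(protein, cond)[0]
                if not math.isnan(t0) and t0 > 0:
                    best = max(best, v.max() / t0)
            else:
                raise ValueError(f"unknown filter mode {mode!r}")
        if not usable:
            log.warning("EGF filter: %s has < 2 time points everywhere; excluded",
                        protein)
            continue
        if best >= threshold:
            kept.append(protein)
    return kept


def score_table(table: TimeCourseTable, threshold: float = 1.5) -> pd.DataFrame:
    """Per-protein score records: A, log2(A), D and the EGF-dependence flag."""
    dependent = set(filter_egf_dependent(table, threshold))
    rows = []
    for protein in table.proteins:
        try:
            a = activation_score(table, protein)
            d = deviation_score(table, protein)
        except ScoreError as e:
            log.warning("scores: %s", e)
            continue
        rows.append((protein, a, math.log2(a) if a > 0 else float("nan"), d,
                     protein in dependent))
    return pd.DataFrame(rows, columns=["protein_id", "A", "log2_A", "D",
                                       "egf_dependent"])


def prepare_for_fitting(table: TimeCourseTable,
                        reference=(WT, ANCHOR_TIME)) -> TimeCourseTable:
    """Normalization chain for comparison with simulations: (1) normalize to
    WT at 5 min; (2) subtract each series' t=0 value; (3) renormalize by the
    post-subtraction WT 5-min value.  Equivalent to
    ``(x(t) - x(0)) / (x_WT(5) - x_WT(0))`` per protein."""
    ref_cond, ref_time = reference
    step1 = normalize_to_reference(table, reference)
    out = step1.copy()
    times = out.times
    ref_ix = np.where(times == ref_time)[0]
    for protein in out.proteins:
        shifted = {}
        for cond in out.conditions:
            if out.has(protein, cond):
                v = out.series(protein, cond)
                shifted[cond] = v - (v[0] if not math.isnan(v[0]) else 0.0)
        denom = None
        if ref_cond in shifted and ref_ix.size:
            denom = shifted[ref_cond][ref_ix[0]]
        if denom is None or math.isnan(denom) or denom <= 0:
            out.flag(protein, "unusable_for_fitting")
            log.warning("prepare_for_fitting: %s has non-positive WT 5-min "
                        "value after baseline subtraction", protein)
            continue
        for cond, v in shifted.items():
            out.data.loc[(protein, cond)] = v / denom
    return out


def fitting_usable_proteins(table: TimeCourseTable) -> list:
    return [p for p in table.proteins
            if "unusable_for_fitting" not in table.flags.get(p, set())]


def rmse(simulated: dict, data: TimeCourseTable, condition: str = WT) -> float:
    """Overall root-mean-square error between simulated series (protein ->
    series aligned to ``data.times``) and the data, pooling all
    protein-time pairs; missing data points are excluded."""
    res = _residuals(simulated, data, condition)
    if not res:
        raise ScoreError("rmse: no overlapping data points")
    pooled = np.concatenate(list(res.values()))
    return float(np.sqrt(np.mean(pooled ** 2)))


def rmse_per_protein(simulated: dict, data: TimeCourseTable,
                     condition: str = WT) -> dict:
    return {p: float(np.sqrt(np.mean(r ** 2)))
            for p, r in _residuals(simulated, data, condition).items()}


def _residuals(simulated, data, condition):
    out = {}
    for protein, sim in simulated.items():
        if not data.has(protein, condition):
            continue
        obs = data.series(protein, condition)
        sim = np.asarray(sim, dtype=float)
        if sim.shape != obs.shape:
            raise ValueError(f"{protein}: simulated series length {sim.shape} "
                             f"does not match data grid {obs.shape}")
        ok = ~np.isnan(obs)
        if ok.any():
            out[protein] = sim[ok] - obs[ok]
    return out
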
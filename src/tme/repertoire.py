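"""TCR-beta repertoire statistics: cpm, clonality, similarity to the timepoint mean.

Clonality is 1 minus Pielou's evenness,

    C = 1 - H'/H,   H' = -sum_i p_i ln p_i  (over templates with count > 0),
    H  = ln(S),     S  = number of distinct templates,

so C = 0 for a perfectly even repertoire and approaches 1 as the repertoire
becomes monoclonal. Similarity of a sample to its cohort at one timepoint is
1 minus the Bray-Curtis distance between the sample's cpm vector and the
cohort mean cpm vector, taken over the union of templates observed at that
timepoint; on presence/absence data this reduces to the Sorensen-Dice index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import RepertoireTable


@dataclass
class ClonalityResult:
    sample_id: str
    S: int
    H_prime: float  # nats
    H_max: float  # ln(S), nats
    C: float  # in [0, 1]


@dataclass
class SimilarityResult:
    sample_id: str
    timepoint: str
    similarity: float  # in [0, 1]
    n_templates_universe: int


def to_cpm(table: RepertoireTable) -> RepertoireTable:
    """Rescale template counts to counts per million (values sum to 1e6)."""
    total = table.counts.sum()
    if total <= 0:
        raise ValueError("cannot cpm-scale an all-zero repertoire")
    return RepertoireTable(
        sample_id=table.sample_id,
        mouse_id=table.mouse_id,
        timepoint=table.timepoint,
        templates=table.templates.copy(),
        counts=table.counts * 1e6 / total,
        is_cpm=True,
    )


def clonality(table: RepertoireTable) -> ClonalityResult:
    """Clonality C = 1 - H'/ln(S) on templates with count > 0.

    Scale-invariant: raw counts and cpm give the same C. The monoclonal
    limit S = 1 leaves C undefined by the formula (H = ln 1 = 0); it is
    defined as 1 here, with a warning, as the limit of minimal evenness.
    """
    counts = table.counts[table.counts > 0]
    if counts.size == 0:
        raise ValueError("repertoire has no template with count > 0")
    S = int(counts.size)
    if np.all(counts == counts[0]):
        # uniform case short-circuit: evenness is exactly 1, so C is exactly 0
        h_prime = float(np.log(S))
    else:
        p = counts / counts.sum()
        h_prime = float(-(p * np.log(p)).sum())
    if S == 1:
        warnings.warn(f"sample {table.sample_id} is monoclonal; clonality set to 1")
        return ClonalityResult(table.sample_id, 1, 0.0, 0.0, 1.0)
    h_max = float(np.log(S))
    return ClonalityResult(table.sample_id, S, h_prime, h_max, 1.0 - h_prime / h_max)


def bray_curtis_similarity(sample: np.ndarray, mean: np.ndarray) -> float:
    """1 - Bray-Curtis distance between two aligned non-negative vectors."""
    sample = np.asarray(sample, float)
    mean = np.asarray(mean, float)
    denom = (sample + mean).sum()
    if denom <= 0:
        raise ValueError("similarity undefined on an empty template universe")
    return float(1.0 - np.abs(sample - mean).sum() / denom)


def _cohort_frame(cohort: list[RepertoireTable]) -> pd.DataFrame:
    """Align cohort cpm vectors on the union of templates observed at the timepoint."""
    series = {}
    for t in cohort:
        tc = t if t.is_cpm else to_cpm(t)
        s = tc.to_series()
        series[t.sample_id] = s[s > 0]
    frame = pd.DataFrame(series).fillna(0.0)
    return frame


def similarity_to_timepoint_mean(
    sample: RepertoireTable,
    cohort: list[RepertoireTable],
    include_self: bool = True,
) -> SimilarityResult:
    """Similarity of one sample to the mean cpm template vector of its cohort.

    The template universe is the union of templates observed (cpm > 0) in any
    cohort sample at the timepoint. By default the focal sample is part of
    the mean; ``include_self=False`` gives the leave-one-out variant.
    """
    timepoints = {t.timepoint for t in cohort} | {sample.timepoint}
    if len(timepoints) > 1:
        raise ValueError(f"cohort mixes timepoints: {sorted(timepoints)}")
    tables = list(cohort)
    if not any(t.sample_id == sample.sample_id for t in tables):
        tables.append(sample)
    frame = _cohort_frame(tables)
    if frame.empty:
        raise ValueError("empty template universe")
    mean_cols = [c for c in frame.columns if include_self or c != sample.sample_id]
    if not mean_cols:
        raise ValueError("cohort mean would average zero samples")
    mean_vec = frame[mean_cols].mean(axis=1).to_numpy()
    sample_vec = frame[sample.sample_id].to_numpy()
    sim = bray_curtis_similarity(sample_vec, mean_vec)
    return SimilarityResult(sample.sample_id, sample.timepoint, sim, len(frame))


def sorensen_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sorensen-Dice index 2|A∩B| / (|A|+|B|) on presence/absence vectors."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both sets empty")
    return float(2.0 * (a & b).sum() / denom)


def longitudinal_summary(
    samples: list[RepertoireTable], include_self: bool = True
) -> pd.DataFrame:
    """Per-(mouse, timepoint) clonality and similarity, with per-mouse deltas.

    Similarity is computed within each timepoint's cohort. The returned table
    has one row per sample plus delta_C / delta_S columns carrying the change
    between the mouse's first and last timepoint (NaN, with a warning, for
    mice observed once). Output is invariant to input order.
    """
    samples = sorted(samples, key=lambda t: (str(t.timepoint), str(t.mouse_id)))
    by_tp: dict[str, list[RepertoireTable]] = {}
    for t in samples:
        by_tp.setdefault(t.timepoint, []).append(t)

    rows = []
    for t in samples:
        c = clonality(t)
        s = similarity_to_timepoint_mean(t, by_tp[t.timepoint], include_self=include_self)
        rows.append(
            {
                "sample_id": t.sample_id,
                "mouse_id": t.mouse_id,
                "timepoint": t.timepoint,
                "S": c.S,
                "H_prime": c.H_prime,
                "clonality": c.C,
                "similarity": s.similarity,
            }
        )
    df = pd.DataFrame(rows)
    df["delta_C"] = np.nan
    df["delta_S"] = np.nan
    for mouse, grp in df.groupby("mouse_id"):
        grp = grp.sort_values("timepoint")
        if len(grp) < 2:
            warnings.warn(f"mouse {mouse} has a single timepoint; delta undefined")
            continue
        first, last = grp.iloc[0], grp.iloc[-1]
        df.loc[grp.index, "delta_C"] = last["clonality"] - first["clonality"]
        df.loc[grp.index, "delta_S"] = last["similarity"] - first["similarity"]
    return df.reset_index(drop=True)
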
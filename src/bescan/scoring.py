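"""Depletion scoring of pooled screen count tables.

One *screen* is one cell line x one editor, with replicate samples at a
baseline (T0) and an endpoint (Tend).  The chain is deliberately simple
and auditable:

1. add a pseudocount to raw counts and normalise each sample to reads per
   million (RPM);
2. average RPM across replicates within each timepoint;
3. discard guides with mean raw T0 reads below a floor (default 100,
   strictly "fewer than": 100 passes, 99 fails);
4. L2FC = log2(mean RPM Tend / mean RPM T0);
5. z = L2FC standardised against the L2FC standard deviation over passing
   guides of the same screen (mean-centred by default).

Negative z means depletion, i.e. a fitness cost of the installed edit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edits import Guide

__all__ = [
    "ScoringParams",
    "ScreenCounts",
    "ScoringError",
    "normalize_and_average",
    "score_guides",
    "score_screen",
    "control_qc",
    "rank_auroc",
]

SCORE_COLUMNS = [
    "guide_id", "mean_rpm_t0", "mean_rpm_end", "raw_t0_mean",
    "l2fc", "z", "pass_filter",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringParams:
    """Tunable scoring parameters.

    pseudocount
        Added to raw counts before RPM normalisation (must be > 0 to keep
        zero-count guides finite).
    min_t0_reads
        Guides with mean raw T0 reads strictly below this are excluded.
    center_z
        If True (default), z = (L2FC - mean) / sd; if False, the literal
        "divide by the standard deviation" reading: z = L2FC / sd.
    hit_z
        Depletion threshold used downstream for hit calling.
    """

    pseudocount: float = 1.0
    min_t0_reads: int = 100
    center_z: bool = True
    hit_z: float = -2.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ScoringError("pseudocount must be > 0")
        if self.min_t0_reads < 0:
            raise ScoringError("min_t0_reads must be >= 0")


@dataclass
class ScreenCounts:
    """Raw counts (guides x samples) plus the sample sheet.

    ``counts`` is indexed by guide_id with one integer column per
    sample_id; ``samples`` has columns sample_id, cell_line, editor,
    timepoint (T0/Tend) and replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.samples["sample_id"]) - set(self.counts.columns)
        if missing:
            raise ScoringError(f"samples absent from count table: {sorted(missing)}")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ScoringError(f"duplicate guide_id in counts: {dup!r}")
        vals = self.counts[list(self.samples["sample_id"])]
        if (vals.to_numpy() < 0).any():
            raise ScoringError("counts must be non-negative")

    def screen(self, cell_line: str, editor: str) -> "ScreenCounts":
        sub = self.samples[
            (self.samples["cell_line"] == cell_line)
            & (self.samples["editor"] == editor)
        ]
        if sub.empty:
            raise ScoringError(f"no samples for screen {cell_line}/{editor}")
        return ScreenCounts(self.counts[list(sub["sample_id"])], sub.reset_index(drop=True))

    @classmethod
    def from_files(cls, counts_path: str, samples_path: str) -> "ScreenCounts":
        counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts, samples)


def _rpm(counts: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    shifted = counts.astype(float) + pseudocount
    total = shifted.sum(axis=0)
    if (total == 0).any():
        raise ScoringError("sample with zero total counts at zero pseudocount")
    return shifted / total * 1e6


def normalize_and_average(
    screen: ScreenCounts, params: ScoringParams
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-guide replicate-mean RPM by timepoint for one screen.

    Returns ``(rpm_means, raw_t0_mean)`` where *rpm_means* has columns
    ``T0`` and ``Tend`` and *raw_t0_mean* is the mean raw (pseudocount-
    free) T0 count used by the read-floor filter.
    """
    by_tp = {}
    for tp in ("T0", "Tend"):
        cols = list(screen.samples.loc[screen.samples["timepoint"] == tp, "sample_id"])
        if not cols:
            raise ScoringError(f"screen has no {tp} samples")
        by_tp[tp] = _rpm(screen.counts[cols], params.pseudocount).mean(axis=1)
    rpm_means = pd.DataFrame(by_tp)
    t0_cols = list(screen.samples.loc[screen.samples["timepoint"] == "T0", "sample_id"])
    raw_t0_mean = screen.counts[t0_cols].mean(axis=1)
    return rpm_means, raw_t0_mean


def score_guides(
    rpm_t0: pd.Series,
    rpm_end: pd.Series,
    raw_t0: pd.Series,
    params: ScoringParams,
) -> pd.DataFrame:
    """L2FC and per-screen z for every guide passing the T0 read floor.

    z is standardised over passing guides only (sample sd, n-1); failing
    guides keep their L2FC but carry z = NaN.
    """
    if not (rpm_t0.index.equals(rpm_end.index) and rpm_t0.index.equals(raw_t0.index)):
        raise ScoringError("timepoint series must share one guide universe")
    pass_filter = raw_t0 >= params.min_t0_reads
    n_pass = int(pass_filter.sum())
    if n_pass < 3:
        raise ScoringError(
            f"only {n_pass} guides pass the T0 read floor; need >= 3 for a z scale"
        )
    l2fc = np.log2(rpm_end / rpm_t0)
    passing = l2fc[pass_filter]
    sd = passing.std(ddof=1)
    if sd == 0:
        raise ScoringError("zero L2FC variance across passing guides")
    center = passing.mean() if params.center_z else 0.0
    z = (l2fc - center) / sd
    z[~pass_filter] = np.nan
    return pd.DataFrame(
        {
            "guide_id": rpm_t0.index,
            "mean_rpm_t0": rpm_t0.to_numpy(),
            "mean_rpm_end": rpm_end.to_numpy(),
            "raw_t0_mean": raw_t0.to_numpy(),
            "l2fc": l2fc.to_numpy(),
            "z": z.to_numpy(),
            "pass_filter": pass_filter.to_numpy(),
        }
    )


def score_screen(
    counts: ScreenCounts,
    params: ScoringParams,
    cell_line: str | None = None,
    editor: str | None = None,
) -> pd.DataFrame:
    """Full chain for one screen, selected by cell line/editor if given."""
    screen = counts
    if cell_line is not None or editor is not None:
        screen = counts.screen(cell_line, editor)
    rpm_means, raw_t0 = normalize_and_average(screen, params)
    return score_guides(rpm_means["T0"], rpm_means["Tend"], raw_t0, params)


def rank_auroc(lower: np.ndarray, higher: np.ndarray) -> float:
    """P(random draw from *lower* < random draw from *higher*), ties 1/2.

    Computed from the Mann-Whitney U statistic; 1.0 means complete
    separation with every *lower* value below every *higher* value.
    """
    lower = np.asarray(lower, dtype=float)
    higher = np.asarray(higher, dtype=float)
    if lower.size == 0 or higher.size == 0:
        raise ScoringError("AUROC needs non-empty groups")
    u = stats.mannwhitneyu(higher, lower, alternative="two-sided").statistic
    return float(u / (lower.size * higher.size))


def control_qc(scores: pd.DataFrame, manifest: list[Guide]) -> dict:
    """Control-based QC of one scored screen.

    Reports median z per control category, the rank AUROC separating
    essential-stop from non-essential-stop controls (probability a random
    essential control scores lower, i.e. more depleted), and the median z
    of non-targeting guides.
    """
    cat = pd.Series({g.guide_id: g.category for g in manifest}, name="category")
    df = scores.join(cat, on="guide_id")
    df = df[df["pass_filter"]]

    def z_of(category: str) -> np.ndarray:
        return df.loc[df["category"] == category, "z"].to_numpy()

    report: dict = {"median_z": {}}
    for category in ("essential_stop_control", "nonessential_stop_control"):
        if z_of(category).size == 0:
            raise ScoringError(f"required control category {category!r} is empty")
    for category in (
        "essential_stop_control",
        "nonessential_stop_control",
        "non_targeting",
        "intergenic",
        "targeting",
    ):
        vals = z_of(category)
        report["median_z"][category] = float(np.median(vals)) if vals.size else None
    report["essential_vs_nonessential_auroc"] = rank_auroc(
        z_of("essential_stop_control"), z_of("nonessential_stop_control")
    )
    report["n_scored"] = {c: int((df["category"] == c).sum())
                          for c in df["category"].unique()}
    return report
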
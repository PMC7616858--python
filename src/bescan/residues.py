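"""Residue-level essentiality maps, enrichment tests and concordance.

Guide depletion z-scores are projected onto the protein: every passing
guide whose combined-mode edit changes the protein contributes its z to
each changed residue; splice-disrupting guides contribute to the exonic
residue flanking the affected intron boundary.  Per residue the default
aggregate is the *minimum* contributing z — a single strongly depleted
guide is enough to mark a residue intolerant — and a residue is a hit
when its aggregate falls at or below the hit threshold.

Enrichment of hits inside a domain (or a pathogenicity class) uses the
one-sided hypergeometric test over the universe of guide-covered
residues: residues no guide reaches are not evidence of tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edits import EditPrediction, PROTEIN_CONSEQUENCES

__all__ = [
    "ResidueMap",
    "DomainTrack",
    "ResidueMapError",
    "build_residue_map",
    "domain_enrichment",
    "pathogenicity_enrichment",
    "screen_concordance",
]

_CONTRIBUTING = (PROTEIN_CONSEQUENCES - {"synonymous"}) | {
    "splice_donor",
    "splice_acceptor",
}


class ResidueMapError(ValueError):
    pass


@dataclass
class DomainTrack:
    """Labelled residue intervals, 1-based inclusive; overlaps allowed."""

    intervals: list[tuple[str, int, int]]

    def residues(self, label: str) -> set[int]:
        out: set[int] = set()
        for lab, s, e in self.intervals:
            if lab == label:
                out.update(range(s, e + 1))
        return out

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab, _, _ in self.intervals:
            if lab not in seen:
                seen.append(lab)
        return seen

    @classmethod
    def from_file(cls, path: str) -> "DomainTrack":
        df = pd.read_csv(path, sep="\t")
        return cls([(str(r.label), int(r.start), int(r.end))
                    for r in df.itertuples(index=False)])

    def to_file(self, path: str) -> None:
        pd.DataFrame(self.intervals, columns=["label", "start", "end"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ResidueMap:
    """Per-residue table plus the long table of guide contributions.

    ``table`` is indexed by residue (1..protein_length) with columns
    aggregate_z, n_guides, hit and the contributing guide ids; residues
    with no contributing guide have NaN aggregate and a null hit call —
    "uncovered" is distinct from "not a hit".
    """

    table: pd.DataFrame
    contributions: pd.DataFrame
    hit_z: float

    @property
    def covered(self) -> pd.Index:
        return self.table.index[self.table["n_guides"] > 0]

    @property
    def hits(self) -> pd.Index:
        return self.table.index[self.table["hit"].fillna(False).astype(bool)]

    def annotate_domains(self, track: DomainTrack) -> None:
        labels = pd.Series("", index=self.table.index, dtype=object)
        for lab, s, e in track.intervals:
            span = labels.loc[s:e]
            labels.loc[s:e] = np.where(span == "", lab, span + ";" + lab)
        self.table["domain"] = labels

    def annotate_pathogenicity(self, scores: pd.DataFrame) -> None:
        """Attach per-residue pathogenicity (columns residue, score, class)."""
        idx = scores.set_index("residue")
        self.table["pathogenicity_score"] = idx["score"].reindex(self.table.index)
        self.table["pathogenicity_class"] = idx["class"].reindex(self.table.index)


def build_residue_map(
    scores: pd.DataFrame,
    predictions: list[EditPrediction],
    protein_length: int,
    hit_z: float = -2.0,
    aggregate: str = "min",
) -> ResidueMap:
    """Project guide z-scores onto residues and call hits.

    Only guides passing the read floor contribute.  Missense/nonsense/
    start-loss/stop-loss guides contribute to every residue in their
    protein changes; splice guides to their flanking exonic residue;
    synonymous, intronic, promoter and no-edit guides to none.
    """
    if aggregate not in ("min", "mean"):
        raise ResidueMapError(f"aggregate must be min or mean, got {aggregate!r}")
    z_by_guide = (
        scores.loc[scores["pass_filter"]].set_index("guide_id")["z"].to_dict()
    )
    rows = []
    for pred in predictions:
        z = z_by_guide.get(pred.guide_id)
        if z is None or not np.isfinite(z):
            continue
        if pred.consequence not in _CONTRIBUTING or pred.consequence == "synonymous":
            continue
        if pred.consequence in ("splice_donor", "splice_acceptor"):
            residues = [] if pred.splice_residue is None else [pred.splice_residue]
        else:
            residues = [pos for pos, _, _ in pred.protein_changes]
            if pred.consequence == "stop_loss":
                # the stop codon sits at position L+1 of the translated CDS;
                # display its disruption on the last real residue
                residues = [min(r, protein_length) for r in residues]
        for res in residues:
            if not (1 <= res <= protein_length):
                raise ResidueMapError(
                    f"guide {pred.guide_id}: residue {res} beyond protein "
                    f"length {protein_length}"
                )
            rows.append(
                {
                    "residue": res,
                    "guide_id": pred.guide_id,
                    "editor": pred.editor,
                    "z": float(z),
                    "consequence": pred.consequence,
                }
            )
    contributions = pd.DataFrame(
        rows, columns=["residue", "guide_id", "editor", "z", "consequence"]
    )
    index = pd.RangeIndex(1, protein_length + 1, name="residue")
    if contributions.empty:
        agg_z = pd.Series(np.nan, index=index)
        n = pd.Series(0, index=index)
    else:
        grouped = contributions.groupby("residue")["z"]
        agg_z = (grouped.min() if aggregate == "min" else grouped.mean()).reindex(index)
        n = grouped.size().reindex(index, fill_value=0)
    hit = pd.Series(pd.NA, index=index, dtype="boolean")
    covered = n > 0
    hit[covered] = agg_z[covered] <= hit_z
    guides = (
        contributions.groupby("residue")["guide_id"]
        .apply(lambda s: ";".join(sorted(s)))
        .reindex(index, fill_value="")
        if not contributions.empty
        else pd.Series("", index=index)
    )
    table = pd.DataFrame(
        {
            "aggregate_z": agg_z,
            "n_guides": n.astype(int),
            "hit": hit,
            "guides": guides,
        },
        index=index,
    )
    return ResidueMap(table=table, contributions=contributions, hit_z=hit_z)


def _enrichment_row(universe: set[int], hits: set[int], label_residues: set[int]) -> dict:
    inside = universe & label_residues
    outside = universe - label_residues
    hits_in = len(hits & inside)
    hits_out = len(hits & outside)
    # P(X >= hits_in), X ~ Hypergeom(|universe|, |hits|, |inside|)
    p = float(stats.hypergeom.sf(hits_in - 1, len(universe), len(hits), len(inside)))
    return {
        "hits_in": hits_in,
        "covered_in": len(inside),
        "hits_out": hits_out,
        "covered_out": len(outside),
        "p": p,
    }


def domain_enrichment(rmap: ResidueMap, track: DomainTrack) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits per domain.

    The universe is the set of guide-covered residues; each label needs at
    least one covered residue inside and outside itself.
    """
    universe = set(rmap.covered)
    if not universe:
        raise ResidueMapError("no guide-covered residues: empty universe")
    hits = set(rmap.hits)
    rows = []
    for label in track.labels:
        res = track.residues(label)
        row = _enrichment_row(universe, hits, res)
        if row["covered_in"] == 0 or row["covered_out"] == 0:
            raise ResidueMapError(
                f"label {label!r} needs covered residues both inside and outside"
            )
        rows.append({"label": label, **row})
    return pd.DataFrame(rows)


def pathogenicity_enrichment(
    rmap: ResidueMap, classes: pd.DataFrame
) -> pd.DataFrame:
    """Hit enrichment per pathogenicity class (columns residue, class).

    Each class (pathogenic / ambiguous / benign) is treated as a label
    over its residues, with the same hypergeometric machinery as domains.
    """
    universe = set(rmap.covered)
    if not universe:
        raise ResidueMapError("no guide-covered residues: empty universe")
    hits = set(rmap.hits)
    rows = []
    for cls_label, sub in classes.groupby("class"):
        res = set(int(r) for r in sub["residue"])
        row = _enrichment_row(universe, hits, res)
        if row["covered_in"] == 0 or row["covered_out"] == 0:
            continue
        rows.append({"label": str(cls_label), **row})
    return pd.DataFrame(rows)


def screen_concordance(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson r, r^2 and n over guides passing filters in both screens."""
    a = scores_a.loc[scores_a["pass_filter"], ["guide_id", "z"]]
    b = scores_b.loc[scores_b["pass_filter"], ["guide_id", "z"]]
    merged = a.merge(b, on="guide_id", suffixes=("_a", "_b")).dropna()
    if len(merged) < 3:
        raise ResidueMapError(
            f"only {len(merged)} guides pass filters in both screens; need >= 3"
        )
    r = float(stats.pearsonr(merged["z_a"], merged["z_b"]).statistic)
    return r, r * r, len(merged)
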
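"""Guide scanning, base-editing outcome prediction and consequence calls.

A base editor deaminates bases of one kind inside a fixed *editing window*
of the protospacer (positions counted 1..20 from the PAM-distal 5' end):
ABE converts A->G and CBE converts C->T on the protospacer strand.  The
*combined* prediction assumes every editable base in the window is
converted simultaneously (the pessimistic bystander assumption used for
scoring); *individual* predictions enumerate single-base outcomes.

Consequences are resolved by re-translating the affected codons of the
gene's coding sequence and assigning the single most disruptive class:

    splice_donor/splice_acceptor > nonsense > start_loss > stop_loss
        > missense > synonymous > promoter > intronic > no_edit
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .gene_model import GeneModel, extract_cds, reverse_complement, splice_sites, translate

__all__ = [
    "EditorSpec",
    "ABE",
    "CBE",
    "Guide",
    "EditPrediction",
    "ControlGuideRecord",
    "EditError",
    "scan_guides",
    "predict_edits",
    "classify_consequence",
    "annotate_guides",
    "rank_control_guides",
    "validate_manifest",
    "read_manifest",
    "write_manifest",
    "predictions_to_frame",
]

GUIDE_LEN = 20

# consequence classes, most disruptive first (splice kinds tie at the top)
CONSEQUENCE_PRIORITY = (
    "splice_donor",
    "splice_acceptor",
    "nonsense",
    "start_loss",
    "stop_loss",
    "missense",
    "synonymous",
    "promoter",
    "intronic",
    "no_edit",
)

PROTEIN_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "nonsense", "start_loss", "stop_loss"}
)

NEUTRAL_CATEGORIES = frozenset({"non_targeting", "intergenic"})

GUIDE_CATEGORIES = (
    "targeting",
    "non_targeting",
    "intergenic",
    "essential_stop_control",
    "nonessential_stop_control",
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class EditError(ValueError):
    """Raised for invalid guides, mismatching references or bad scores."""


@dataclass(frozen=True)
class EditorSpec:
    """A base editor: its conversion chemistry, window and PAM.

    ``window`` is inclusive over protospacer positions 1..20 counted from
    the PAM-distal 5' end; the conversion applies on the protospacer
    strand.  Defaults follow the conventional high-activity window of
    NGN-PAM editors.
    """

    name: str
    ref_base: str
    alt_base: str
    window: tuple[int, int] = (4, 8)
    pam_pattern: str = "NGN"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= GUIDE_LEN):
            raise EditError(f"window {self.window} outside 1..{GUIDE_LEN}")
        if len(self.pam_pattern) != 3:
            raise EditError(f"PAM pattern must be 3 nt, got {self.pam_pattern!r}")


ABE = EditorSpec("ABE", "A", "G")
CBE = EditorSpec("CBE", "C", "T")

EDITORS = {"ABE": ABE, "CBE": CBE}


def pam_matches(pam: str, pattern: str) -> bool:
    return len(pam) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(pam.upper(), pattern.upper())
    )


@dataclass
class Guide:
    """A 20-nt protospacer with its PAM and library category.

    ``contig_start`` is the 0-based leftmost contig position of the
    protospacer (``None`` for non-positional controls); ``protospacer``
    is always given 5'->3' on the protospacer strand.
    """

    guide_id: str
    protospacer: str
    pam: str
    contig_start: int | None
    strand: str
    category: str = "targeting"

    def protospacer_to_contig(self, pos: int) -> int:
        """Map protospacer position (1..20, PAM-distal 5' end = 1) to contig."""
        if self.contig_start is None:
            raise EditError(f"guide {self.guide_id} has no contig position")
        if self.strand == "+":
            return self.contig_start + pos - 1
        return self.contig_start + GUIDE_LEN - pos


@dataclass
class EditPrediction:
    """Predicted edits of one guide under one editor, with consequence.

    ``edited_positions`` holds ``(protospacer_pos, contig_pos, ref, alt)``
    with ref/alt expressed on the contig plus strand.  ``splice_residue``
    is the exonic residue flanking a disrupted splice core (set only for
    splice consequences) and is what residue-level maps use for splice
    guides.
    """

    guide_id: str
    editor: str
    edited_positions: list[tuple[int, int, str, str]]
    mode: str = "combined"
    consequence: str = "no_edit"
    protein_changes: list[tuple[int, str, str]] = field(default_factory=list)
    installs_proline: bool = False
    splice_residue: int | None = None
    intron_index: int | None = None


@dataclass
class ControlGuideRecord:
    """Splice-disruption control guide with external scoring inputs.

    The selection metric is ``m = d * (ABEscore + CBEscore)`` where *d* is
    the cDNA disruption score in [0, 1]; the external scores are inputs,
    never recomputed here.
    """

    guide_id: str
    gene_id: str
    cdna_disruption_score: float
    abe_score: float
    cbe_score: float

    @property
    def metric(self) -> float:
        return self.cdna_disruption_score * (self.abe_score + self.cbe_score)


# ---------------------------------------------------------------------------
# scanning


def scan_guides(
    model: GeneModel,
    editor: EditorSpec,
    region: tuple[int, int] | str = "all",
) -> list[Guide]:
    """Find every NGN-PAM protospacer on both strands of the contig.

    ``region`` restricts to protospacers overlapping the 0-based half-open
    interval.  Order is deterministic: contig position, then ``+`` before
    ``-``.
    """
    seq = model.contig_seq
    n = len(seq)
    if region == "all":
        lo, hi = 0, n
    else:
        lo, hi = region
        if not (0 <= lo < hi <= n):
            raise EditError(f"region [{lo},{hi}) outside contig of length {n}")

    guides: list[Guide] = []
    for start in range(n - GUIDE_LEN + 1):
        end = start + GUIDE_LEN
        if end <= lo or start >= hi:
            continue
        # plus strand: PAM immediately 3' of the protospacer
        if end + 3 <= n:
            pam = seq[end : end + 3]
            if pam_matches(pam, editor.pam_pattern):
                guides.append(
                    Guide(
                        guide_id=f"{model.contig_id}:{start + 1}:+",
                        protospacer=seq[start:end],
                        pam=pam,
                        contig_start=start,
                        strand="+",
                        category="targeting",
                    )
                )
        # minus strand: PAM is the reverse complement of the 3 nt 5' of start
        if start - 3 >= 0:
            pam = reverse_complement(seq[start - 3 : start])
            if pam_matches(pam, editor.pam_pattern):
                guides.append(
                    Guide(
                        guide_id=f"{model.contig_id}:{start + 1}:-",
                        protospacer=reverse_complement(seq[start:end]),
                        pam=pam,
                        contig_start=start,
                        strand="-",
                        category="targeting",
                    )
                )
    return guides


# ---------------------------------------------------------------------------
# prediction


def _window_edits(
    guide: Guide, editor: EditorSpec, contig_seq: str | None
) -> list[tuple[int, int, str, str]]:
    """Editable bases in the window as contig-plus-strand substitutions."""
    if guide.category in NEUTRAL_CATEGORIES or guide.contig_start is None:
        return []
    if contig_seq is not None:
        ref = contig_seq[guide.contig_start : guide.contig_start + GUIDE_LEN]
        if guide.strand == "-":
            ref = reverse_complement(ref)
        for i, (a, b) in enumerate(zip(guide.protospacer.upper(), ref)):
            if a != b:
                raise EditError(
                    f"guide {guide.guide_id}: protospacer mismatches reference "
                    f"at protospacer position {i + 1} ({a} vs {b})"
                )
    edits = []
    lo, hi = editor.window
    for pos in range(lo, hi + 1):
        base = guide.protospacer[pos - 1].upper()
        if base != editor.ref_base:
            continue
        cpos = guide.protospacer_to_contig(pos)
        ref, alt = editor.ref_base, editor.alt_base
        if guide.strand == "-":
            ref, alt = reverse_complement(ref), reverse_complement(alt)
        edits.append((pos, cpos, ref, alt))
    return edits


def predict_edits(
    guide: Guide,
    editor: EditorSpec,
    contig_seq: str | None = None,
    mode: str = "combined",
) -> EditPrediction | list[EditPrediction]:
    """Predict editor-specific edits for a guide.

    Combined mode converts every editable base in the window at once and
    returns one prediction; individual mode returns one prediction per
    editable base.  Passing ``contig_seq`` verifies the protospacer
    against the reference (targeting guides).
    """
    if mode not in ("combined", "individual"):
        raise EditError(f"mode must be combined or individual, got {mode!r}")
    edits = _window_edits(guide, editor, contig_seq)
    if mode == "combined":
        return EditPrediction(guide.guide_id, editor.name, edits, mode="combined")
    return [
        EditPrediction(guide.guide_id, editor.name, [e], mode="individual")
        for e in edits
    ]


# ---------------------------------------------------------------------------
# consequence classification


def _splice_flank_residue(model: GeneModel, intron_idx: int, kind: str) -> int | None:
    """1-based residue flanking an intron boundary on its exonic side."""
    cds_pos = model.cds_positions()
    if not cds_pos:
        return None
    intron = model.introns[intron_idx]
    # exonic contig position adjacent to the disrupted core, coding-strand side
    if model.strand == "+":
        flank = intron[0] - 1 if kind == "splice_donor" else intron[1]
    else:
        flank = intron[1] if kind == "splice_donor" else intron[0] - 1
    idx = model.cds_index(flank)
    if idx is None:
        # boundary falls in a non-coding exon part: use nearest coding base
        idx = min(
            range(len(cds_pos)), key=lambda i: abs(cds_pos[i] - flank)
        )
    return idx // 3 + 1


def classify_consequence(
    prediction: EditPrediction, model: GeneModel
) -> EditPrediction:
    """Resolve a prediction's consequence and protein changes.

    Applies the edits to the contig, re-translates affected codons and
    assigns the highest-priority class.  Edits outside the gene footprint
    classify as ``no_edit`` (with the other edits still considered).
    """
    if not prediction.edited_positions:
        return replace(prediction, consequence="no_edit", protein_changes=[],
                       installs_proline=False)

    donors = {p for p, k, _ in splice_sites(model) if k == "donor"}
    acceptors = {p for p, k, _ in splice_sites(model) if k == "acceptor"}

    zones: set[str] = set()
    splice_kind: str | None = None
    splice_intron: int | None = None
    cds_hit = False
    for _, cpos, ref, alt in prediction.edited_positions:
        if cpos in donors or cpos in acceptors:
            kind = "splice_donor" if cpos in donors else "splice_acceptor"
            if splice_kind is None or CONSEQUENCE_PRIORITY.index(kind) < \
                    CONSEQUENCE_PRIORITY.index(splice_kind):
                splice_kind = kind
                splice_intron = next(
                    i for i, (s, e) in enumerate(model.introns) if s <= cpos < e
                )
        if model.cds_index(cpos) is not None:
            cds_hit = True
        elif model.in_intron(cpos):
            zones.add("intronic")
        elif model.in_promoter(cpos):
            zones.add("promoter")
        else:
            zones.add("no_edit")  # outside gene footprint

    # protein-level diff over the affected codons
    protein_changes: list[tuple[int, str, str]] = []
    protein_class: str | None = None
    if cds_hit:
        seq = list(model.contig_seq)
        for _, cpos, ref, alt in prediction.edited_positions:
            if seq[cpos] != ref:
                raise EditError(
                    f"guide {prediction.guide_id}: reference base at contig "
                    f"position {cpos + 1} is {seq[cpos]}, expected {ref}"
                )
            seq[cpos] = alt
        edited = replace_contig(model, "".join(seq))
        ref_prot = translate(extract_cds(model))
        alt_prot = translate(extract_cds(edited))
        affected = sorted(
            {
                model.cds_index(cpos) // 3
                for _, cpos, _, _ in prediction.edited_positions
                if model.cds_index(cpos) is not None
            }
        )
        changed = [i for i in range(len(ref_prot)) if ref_prot[i] != alt_prot[i]]
        if changed:
            protein_changes = [(i + 1, ref_prot[i], alt_prot[i]) for i in changed]
            last = len(ref_prot) - 1
            if any(ref_prot[i] != "*" and alt_prot[i] == "*" for i in changed):
                protein_class = "nonsense"
            elif 0 in changed and ref_prot[0] == "M":
                protein_class = "start_loss"
            elif last in changed and ref_prot[last] == "*":
                protein_class = "stop_loss"
            else:
                protein_class = "missense"
        else:
            protein_class = "synonymous"
            protein_changes = [(i + 1, ref_prot[i], ref_prot[i]) for i in affected]

    if splice_kind is not None:
        consequence = splice_kind
    elif protein_class is not None:
        consequence = protein_class
    elif "promoter" in zones:
        consequence = "promoter"
    elif "intronic" in zones:
        consequence = "intronic"
    else:
        consequence = "no_edit"

    if consequence not in PROTEIN_CONSEQUENCES:
        protein_changes_out: list[tuple[int, str, str]] = []
    else:
        protein_changes_out = protein_changes

    installs_proline = any(
        alt == "P" and ref != alt for _, ref, alt in protein_changes_out
    )
    splice_residue = None
    if consequence in ("splice_donor", "splice_acceptor"):
        splice_residue = _splice_flank_residue(model, splice_intron, consequence)

    return replace(
        prediction,
        consequence=consequence,
        protein_changes=protein_changes_out,
        installs_proline=installs_proline,
        splice_residue=splice_residue,
        intron_index=splice_intron,
    )


def replace_contig(model: GeneModel, new_seq: str) -> GeneModel:
    """Copy of the model over an edited contig (protein re-derived lazily)."""
    return GeneModel(
        gene_id=model.gene_id,
        contig_id=model.contig_id,
        contig_seq=new_seq,
        strand=model.strand,
        exons=list(model.exons),
        cds=list(model.cds),
        promoter=model.promoter,
        protein="-",  # sentinel: edited proteins may contain internal stops
    )


def annotate_guides(
    guides: list[Guide], editor: EditorSpec, model: GeneModel
) -> list[EditPrediction]:
    """Combined-mode prediction + consequence for a whole library."""
    out = []
    for g in guides:
        contig = model.contig_seq if g.category == "targeting" else None
        pred = predict_edits(g, editor, contig_seq=contig, mode="combined")
        out.append(classify_consequence(pred, model))
    return out


# ---------------------------------------------------------------------------
# control-guide ranking


def rank_control_guides(
    records: list[ControlGuideRecord], per_gene_top_k: int = 3
) -> list[ControlGuideRecord]:
    """Top-k control guides per gene by m = d * (ABEscore + CBEscore).

    Descending by metric; ties broken by guide_id lexicographically.
    """
    import math

    for r in records:
        for v in (r.cdna_disruption_score, r.abe_score, r.cbe_score):
            if not math.isfinite(v):
                raise EditError(f"non-finite score on guide {r.guide_id}")
        if r.cdna_disruption_score < 0:
            raise EditError(
                f"negative cDNA disruption score on guide {r.guide_id}"
            )
    out: list[ControlGuideRecord] = []
    by_gene: dict[str, list[ControlGuideRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gene in sorted(by_gene):
        ranked = sorted(by_gene[gene], key=lambda r: (-r.metric, r.guide_id))
        out.extend(ranked[:per_gene_top_k])
    return out


# ---------------------------------------------------------------------------
# manifest validation and I/O


def validate_manifest(
    manifest: list[Guide],
    model: GeneModel | None = None,
    pam_pattern: str = "NGN",
) -> dict:
    """Category counts plus duplicate and invalid-guide listings.

    Never repairs anything: duplicates raise, invalid PAMs and reference
    mismatches are listed in the report.
    """
    seen: set[str] = set()
    for g in manifest:
        if g.guide_id in seen:
            raise EditError(f"duplicate guide_id {g.guide_id!r} in manifest")
        seen.add(g.guide_id)

    counts = {c: 0 for c in GUIDE_CATEGORIES}
    invalid_pam: list[str] = []
    mismatched: list[str] = []
    for g in manifest:
        counts[g.category] = counts.get(g.category, 0) + 1
        if g.category == "targeting":
            if not pam_matches(g.pam, pam_pattern):
                invalid_pam.append(g.guide_id)
            if model is not None and g.contig_start is not None:
                ref = model.contig_seq[g.contig_start : g.contig_start + GUIDE_LEN]
                if g.strand == "-":
                    ref = reverse_complement(ref)
                if ref != g.protospacer.upper():
                    mismatched.append(g.guide_id)
    return {
        "n_guides": len(manifest),
        "category_counts": counts,
        "invalid_pam": invalid_pam,
        "reference_mismatch": mismatched,
    }


_MANIFEST_COLS = [
    "guide_id", "protospacer", "pam", "contig", "start_1based", "strand", "category",
]


def write_manifest(guides: list[Guide], path: str, contig_id: str) -> None:
    rows = []
    for g in guides:
        rows.append(
            {
                "guide_id": g.guide_id,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "contig": contig_id if g.contig_start is not None else ".",
                "start_1based": 0 if g.contig_start is None else g.contig_start + 1,
                "strand": g.strand,
                "category": g.category,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> list[Guide]:
    df = pd.read_csv(path, sep="\t", dtype={"start_1based": int})
    guides = []
    for row in df.itertuples(index=False):
        start = None if row.start_1based == 0 else int(row.start_1based) - 1
        guides.append(
            Guide(
                guide_id=str(row.guide_id),
                protospacer=str(row.protospacer),
                pam=str(row.pam),
                contig_start=start,
                strand=str(row.strand),
                category=str(row.category),
            )
        )
    return guides


def predictions_to_frame(predictions: list[EditPrediction]) -> pd.DataFrame:
    """Tidy per-guide prediction table (1-based contig positions)."""
    rows = []
    for p in predictions:
        rows.append(
            {
                "guide_id": p.guide_id,
                "editor": p.editor,
                "mode": p.mode,
                "edits": ";".join(
                    f"{cpos + 1}:{ref}>{alt}" for _, cpos, ref, alt in p.edited_positions
                ),
                "consequence": p.consequence,
                "protein_changes": ";".join(
                    f"{ref}{pos}{alt}" for pos, ref, alt in p.protein_changes
                ),
                "installs_proline": p.installs_proline,
                "splice_residue": "" if p.splice_residue is None else p.splice_residue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "guide_id", "editor", "mode", "edits", "consequence",
            "protein_changes", "installs_proline", "splice_residue",
        ],
    )
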
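"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles against the stated
contracts — full-contig mutation, whole-CDS re-extraction and
re-translation, straight-line normalisation arithmetic, exhaustive
enumeration for the hypergeometric test — and deliberately shares no
code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

PRIORITY = [
    "splice_donor", "splice_acceptor", "nonsense", "start_loss", "stop_loss",
    "missense", "synonymous", "promoter", "intronic", "no_edit",
]


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def brute_force_consequence(model, guide, editor):
    """Re-derive a combined-mode consequence by mutating the whole contig.

    Returns (consequence, protein_changes, installs_proline).
    """
    # 1. enumerate editable window bases by hand
    edits = []  # (contig_pos, ref_on_plus, alt_on_plus)
    lo, hi = editor.window
    for p in range(lo, hi + 1):
        if guide.protospacer[p - 1] != editor.ref_base:
            continue
        if guide.strand == "+":
            cpos = guide.contig_start + (p - 1)
            ref, alt = editor.ref_base, editor.alt_base
        else:
            cpos = guide.contig_start + (20 - p)
            ref, alt = _COMP[editor.ref_base], _COMP[editor.alt_base]
        edits.append((cpos, ref, alt))
    if not edits:
        return "no_edit", [], False

    # 2. mutate the full contig string
    seq = list(model.contig_seq)
    for cpos, ref, alt in edits:
        assert seq[cpos] == ref, "oracle: reference mismatch"
        seq[cpos] = alt
    edited_contig = "".join(seq)

    # 3. locate edits: splice cores, CDS, introns, promoter
    introns = [
        (model.exons[i][1], model.exons[i + 1][0])
        for i in range(len(model.exons) - 1)
    ]
    donor_hit = acceptor_hit = False
    for s, e in introns:
        if model.strand == "+":
            donor, acceptor = {s, s + 1}, {e - 2, e - 1}
        else:
            donor, acceptor = {e - 1, e - 2}, {s, s + 1}
        for cpos, _, _ in edits:
            if cpos in donor:
                donor_hit = True
            if cpos in acceptor:
                acceptor_hit = True

    cds_pos = [p for s, e in model.cds for p in range(s, e)]
    if model.strand == "-":
        cds_pos = cds_pos[::-1]
    cds_index = {p: i for i, p in enumerate(cds_pos)}
    in_cds = [c for c, _, _ in edits if c in cds_index]
    in_intron = any(
        s <= c < e for c, _, _ in edits for s, e in introns
    )
    in_promoter = model.promoter is not None and any(
        model.promoter[0] <= c < model.promoter[1] for c, _, _ in edits
    )

    # 4. re-extract and re-translate the entire CDS, diff proteins
    def cds_seq(contig: str) -> str:
        s = "".join(contig[p] for p in sorted(cds_index, key=cds_index.get))
        return s

    changes = []
    protein_class = None
    installs_proline = False
    if in_cds:
        ref_prot = str(Seq(cds_seq(model.contig_seq)).translate())
        alt_prot = str(Seq(cds_seq(edited_contig)).translate())
        assert len(ref_prot) == len(alt_prot)
        changes = [
            (i + 1, ref_prot[i], alt_prot[i])
            for i in range(len(ref_prot))
            if ref_prot[i] != alt_prot[i]
        ]
        if changes:
            if any(r != "*" and a == "*" for _, r, a in changes):
                protein_class = "nonsense"
            elif any(pos == 1 and r == "M" for pos, r, _ in changes):
                protein_class = "start_loss"
            elif any(
                pos == len(ref_prot) and r == "*" for pos, r, _ in changes
            ):
                protein_class = "stop_loss"
            else:
                protein_class = "missense"
        else:
            protein_class = "synonymous"
            codons = sorted({cds_index[c] // 3 for c in in_cds})
            changes = [(i + 1, ref_prot[i], ref_prot[i]) for i in codons]

    # 5. priority resolution
    if donor_hit:
        consequence = "splice_donor"
    elif acceptor_hit:
        consequence = "splice_acceptor"
    elif protein_class is not None:
        consequence = protein_class
    elif in_promoter:
        consequence = "promoter"
    elif in_intron:
        consequence = "intronic"
    else:
        consequence = "no_edit"

    if consequence not in {"synonymous", "missense", "nonsense", "start_loss",
                           "stop_loss"}:
        changes = []
    installs_proline = any(a == "P" and r != a for _, r, a in changes)
    return consequence, changes, installs_proline


def straight_line_scores(counts, t0_cols, tend_cols, pseudocount, min_t0, center):
    """Plain-loop recomputation of the RPM -> mean -> L2FC -> z chain.

    ``counts`` is a dict guide_id -> list of raw counts ordered as
    t0_cols + tend_cols.  Returns dict guide_id -> (l2fc, z or None).
    """
    guide_ids = list(counts)
    n_samples = len(t0_cols) + len(tend_cols)
    rpm = {g: [0.0] * n_samples for g in guide_ids}
    for j in range(n_samples):
        total = sum(counts[g][j] + pseudocount for g in guide_ids)
        for g in guide_ids:
            rpm[g][j] = (counts[g][j] + pseudocount) / total * 1e6
    nt0 = len(t0_cols)
    out = {}
    passing = []
    for g in guide_ids:
        mean_t0 = sum(rpm[g][:nt0]) / nt0
        mean_end = sum(rpm[g][nt0:]) / len(tend_cols)
        raw_t0 = sum(counts[g][:nt0]) / nt0
        l2fc = math.log2(mean_end / mean_t0)
        ok = raw_t0 >= min_t0
        out[g] = [l2fc, None, ok]
        if ok:
            passing.append(g)
    vals = [out[g][0] for g in passing]
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    for g in passing:
        out[g][1] = (out[g][0] - (mean if center else 0.0)) / sd
    return {g: (l, z) for g, (l, z, _) in out.items()}


def enumerate_hypergeom_p(universe_size, n_hits, label_size, hits_in):
    """P(overlap >= hits_in) by exhaustive enumeration of hit placements."""
    universe = range(universe_size)
    label = set(range(label_size))
    total = 0
    at_least = 0
    for hits in itertools.combinations(universe, n_hits):
        total += 1
        if len(label & set(hits)) >= hits_in:
            at_least += 1
    return at_least / total
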
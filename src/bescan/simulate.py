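"""Synthetic saturation-mutagenesis screens with known ground truth.

The generator builds a WRN-like test bed end to end: a random single-gene
contig with canonical GT..AG introns and an upstream promoter, the full
NGN guide library tiling its exons and promoter plus the four control
categories, a ground-truth effect per (guide, editor), and overdispersed
count tables for every screen.

Effect model
------------
A set of *essential residues* (by default a fraction of the protein,
drawn inside a helicase-like core domain) defines the truth: a guide is
deleterious in a given editor's screen iff its combined-mode edit changes
at least one essential residue (splice disruption counts via the flanking
exonic residue), in which case its true L2FC is ``l2fc_essential`` scaled
by a per-guide Beta-distributed efficiency.  Synonymous, intronic,
promoter and no-edit outcomes — and the non-targeting / intergenic /
non-essential-stop control categories — are exactly neutral.
Essential-stop controls deplete at ``l2fc_stop_essential_control`` times
their efficiency regardless of the gene.

Noise model
-----------
Per screen, T0 abundances are lognormal around the target coverage;
endpoint means are the T0 share times ``2**true_l2fc`` times depth;
counts are negative binomial with variance ``mu + dispersion * mu**2``,
drawn independently per replicate.  All draws flow from one seeded
generator, so a config reproduces itself byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edits import (
    ABE,
    CBE,
    EditorSpec,
    Guide,
    annotate_guides,
    scan_guides,
)
from .gene_model import GeneModel
from .residues import DomainTrack
from .scoring import ScreenCounts

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulationError",
    "simulate_gene_and_library",
    "simulate_screen_counts",
    "default_domain_track",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic study.

    Defaults mirror the emulated screen design: ~1000x T0 coverage, two
    replicates, two editors, two cell lines, a tiled exon/promoter
    library plus control categories at the emulated library's sizes.
    """

    seed: int = 0
    # gene shape
    n_exons: int = 8
    exon_length: int = 540          # bp per exon (CDS == exons here)
    intron_length: int = 120
    promoter_length: int = 300
    flank: int = 60
    # screen design
    coverage: float = 1000.0        # expected T0 reads per guide
    n_replicates: int = 2
    editors: tuple[str, ...] = ("ABE", "CBE")
    cell_lines: tuple[str, ...] = ("LINE_A", "LINE_B")
    # effect model
    l2fc_essential: float = -2.0
    l2fc_neutral: float = 0.0
    l2fc_stop_essential_control: float = -3.0
    efficiency_alpha: float = 5.0
    efficiency_beta: float = 2.0
    # essential residues: int = count, float in (0,1) = fraction of protein
    essential_residues: int | float | frozenset = 0.10
    # where essential residues may land (fractions of protein length);
    # uniform over the protein interior by default so that two truth draws
    # are statistically independent; narrow the span (e.g. to a
    # helicase-like core) to emulate domain-concentrated intolerance
    essential_domain_span: tuple[float, float] = (0.02, 0.98)
    # noise
    dispersion: float = 0.01        # NB alpha: var = mu + alpha * mu^2
    abundance_sigma: float = 0.30   # lognormal sd of T0 abundance (log scale)
    # control categories (library composition being emulated)
    n_non_targeting: int = 57
    n_intergenic: int = 168
    n_essential_stop: int = 307
    n_nonessential_stop: int = 87
    window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise SimulationError("coverage must be > 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if (self.exon_length * self.n_exons) % 3 != 0:
            raise SimulationError(
                f"total exon length {self.exon_length * self.n_exons} "
                "does not yield a CDS divisible by 3"
            )

    def editor_specs(self) -> list[EditorSpec]:
        base = {"ABE": ABE, "CBE": CBE}
        return [
            EditorSpec(name, base[name].ref_base, base[name].alt_base,
                       window=self.window)
            for name in self.editors
        ]


@dataclass
class TruthSet:
    """Ground truth behind a simulated study.

    ``guides`` has one row per (guide, editor): consequence, affected
    residues, per-guide efficiency and true L2FC.  ``essential_residues``
    is the injected intolerant set (1-based).
    """

    guides: pd.DataFrame
    essential_residues: frozenset[int]

    def true_l2fc(self, editor: str) -> pd.Series:
        sub = self.guides[self.guides["editor"] == editor]
        return sub.set_index("guide_id")["true_l2fc"]

    def validate(self) -> None:
        neutral = self.guides["category"].isin(["non_targeting", "intergenic"])
        neutral |= self.guides["consequence"].isin(
            ["synonymous", "intronic", "promoter", "no_edit"]
        ) & (self.guides["category"] == "targeting")
        bad = self.guides.loc[neutral & (self.guides["true_l2fc"] != 0)]
        if not bad.empty:
            raise SimulationError(
                f"neutral guides with nonzero truth: {list(bad['guide_id'][:3])}"
            )

    def to_file(self, path: str) -> None:
        self.guides.to_csv(path, sep="\t", index=False)
        # essential set rides along as a commented footer-free sidecar column
        # (kept in the frame via the 'essential' indicator instead)


def _random_gene(config: SimulationConfig, rng: np.random.Generator) -> GeneModel:
    """Random plus-strand gene: promoter + exons separated by GT..AG introns."""
    n_codons = config.exon_length * config.n_exons // 3
    codons = ["ATG"] + [
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 2)
    ] + ["TAA"]
    cds = "".join(codons)

    def random_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    parts = [random_seq(config.flank), random_seq(config.promoter_length)]
    promoter = (config.flank, config.flank + config.promoter_length)
    pos = promoter[1]
    exons: list[tuple[int, int]] = []
    for i in range(config.n_exons):
        chunk = cds[i * config.exon_length : (i + 1) * config.exon_length]
        parts.append(chunk)
        exons.append((pos, pos + len(chunk)))
        pos += len(chunk)
        if i < config.n_exons - 1:
            intron = "GT" + random_seq(config.intron_length - 4) + "AG"
            parts.append(intron)
            pos += len(intron)
    parts.append(random_seq(config.flank))
    model = GeneModel(
        gene_id="WRN_like",
        contig_id="chr_sim",
        contig_seq="".join(parts),
        strand="+",
        exons=exons,
        cds=list(exons),
        promoter=promoter,
    )
    model.validate(strict_splice=True)
    return model


def _draw_essential(
    config: SimulationConfig, protein_length: int, rng: np.random.Generator
) -> frozenset[int]:
    spec = config.essential_residues
    if isinstance(spec, frozenset):
        return spec
    lo = max(2, int(config.essential_domain_span[0] * protein_length))
    hi = min(protein_length - 1, int(config.essential_domain_span[1] * protein_length))
    pool = np.arange(lo, hi + 1)
    if isinstance(spec, float) and 0 < spec < 1:
        k = int(round(spec * protein_length))
    else:
        k = int(spec)
    if k > pool.size:
        raise SimulationError(
            f"cannot place {k} essential residues in a pool of {pool.size}"
        )
    return frozenset(int(r) for r in rng.choice(pool, size=k, replace=False))


def default_domain_track(protein_length: int) -> DomainTrack:
    """WRN-style domain layout scaled to the synthetic protein length."""
    L = protein_length

    def span(a: float, b: float) -> tuple[int, int]:
        return max(1, int(a * L)), min(L, int(b * L))

    return DomainTrack(
        intervals=[
            ("exonuclease", *span(0.02, 0.16)),
            ("helicase_ATP", *span(0.35, 0.60)),
            ("RQC", *span(0.65, 0.78)),
            ("HRDC", *span(0.80, 0.90)),
        ]
    )


def simulate_gene_and_library(
    config: SimulationConfig,
    truth_seed: int | None = None,
) -> tuple[GeneModel, list[Guide], TruthSet]:
    """Gene model, tiled guide library with controls, and ground truth.

    Targeting guides are every NGN protospacer overlapping exons or the
    promoter; truth is assigned by running the package's own edit
    prediction on the synthetic model.  ``truth_seed`` redraws the
    stochastic truth (essential residues, guide efficiencies) over the
    *same* gene and library — two truth seeds on one config yield screens
    with independent ground truth but identical guide universes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    rng_truth = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed if truth_seed is None else truth_seed, 1]
        )
    )
    model = _random_gene(config, rng)
    protein_length = len(model.protein)
    essential = _draw_essential(config, protein_length, rng_truth)

    lo, hi = model.footprint
    scanned = scan_guides(model, config.editor_specs()[0], region=(lo, hi))
    # keep protospacers overlapping exons or promoter
    spans = list(model.exons) + ([model.promoter] if model.promoter else [])
    targeting = []
    for g in scanned:
        s, e = g.contig_start, g.contig_start + 20
        if any(s < se and ss < e for ss, se in spans):
            targeting.append(g)
    for i, g in enumerate(targeting, 1):
        g.guide_id = f"WRN_like_sg{i:05d}"

    def control_block(prefix: str, n: int, category: str) -> list[Guide]:
        out = []
        for i in range(1, n + 1):
            proto = "".join("ACGT"[j] for j in rng.integers(0, 4, size=20))
            pam = "ACGT"[rng.integers(0, 4)] + "G" + "ACGT"[rng.integers(0, 4)]
            out.append(
                Guide(
                    guide_id=f"{prefix}{i:04d}",
                    protospacer=proto,
                    pam=pam,
                    contig_start=None,
                    strand="+",
                    category=category,
                )
            )
        return out

    manifest = (
        targeting
        + control_block("NT", config.n_non_targeting, "non_targeting")
        + control_block("IG", config.n_intergenic, "intergenic")
        + control_block("ESS", config.n_essential_stop, "essential_stop_control")
        + control_block("NON", config.n_nonessential_stop, "nonessential_stop_control")
    )

    efficiency = {
        g.guide_id: float(
            rng_truth.beta(config.efficiency_alpha, config.efficiency_beta)
        )
        for g in manifest
    }

    rows = []
    for editor in config.editor_specs():
        predictions = annotate_guides(manifest, editor, model)
        for g, pred in zip(manifest, predictions):
            if pred.consequence in ("splice_donor", "splice_acceptor"):
                residues = [] if pred.splice_residue is None else [pred.splice_residue]
            elif pred.consequence in ("missense", "nonsense", "start_loss", "stop_loss"):
                residues = [pos for pos, _, _ in pred.protein_changes]
            else:
                residues = []
            eff = efficiency[g.guide_id]
            if g.category == "essential_stop_control":
                l2fc = config.l2fc_stop_essential_control * eff
            elif g.category == "targeting" and any(r in essential for r in residues):
                l2fc = config.l2fc_essential * eff
            else:
                l2fc = config.l2fc_neutral
            rows.append(
                {
                    "guide_id": g.guide_id,
                    "editor": editor.name,
                    "category": g.category,
                    "consequence": pred.consequence if g.category == "targeting"
                    else "no_edit",
                    "residues": ";".join(str(r) for r in residues)
                    if g.category == "targeting" else "",
                    "essential": any(r in essential for r in residues)
                    if g.category == "targeting" else False,
                    "efficiency": eff,
                    "true_l2fc": l2fc,
                }
            )
    truth = TruthSet(
        guides=pd.DataFrame(rows), essential_residues=essential
    )
    truth.validate()
    return model, manifest, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    manifest: list[Guide],
    truth: TruthSet,
    config: SimulationConfig,
    noise_seed: int | None = None,
) -> ScreenCounts:
    """Overdispersed count tables for every (cell line x editor) screen.

    ``noise_seed`` (default: the config seed) isolates the count noise
    stream so independent realisations over one truth can be drawn.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed if noise_seed is None else noise_seed, 2**20]
        )
    )
    guide_ids = [g.guide_id for g in manifest]
    n = len(guide_ids)
    depth = config.coverage * n

    counts: dict[str, np.ndarray] = {}
    samples = []
    for cell_line in config.cell_lines:
        for editor in config.editors:
            l2fc = truth.true_l2fc(editor).reindex(guide_ids).to_numpy()
            if np.isnan(l2fc).any():
                raise SimulationError("truth missing for some manifest guides")
            sigma = config.abundance_sigma
            abundance = config.coverage * rng.lognormal(
                -0.5 * sigma**2, sigma, size=n
            )
            t0_share = abundance / abundance.sum()
            end_mean = t0_share * np.power(2.0, l2fc) * depth
            for rep in range(1, config.n_replicates + 1):
                for tp, mean in (("T0", abundance), ("Tend", end_mean)):
                    sid = f"{cell_line}_{editor}_{tp}_R{rep}"
                    counts[sid] = _nb_draw(rng, mean, config.dispersion)
                    samples.append(
                        {
                            "sample_id": sid,
                            "cell_line": cell_line,
                            "editor": editor,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    counts_df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    return ScreenCounts(counts=counts_df, samples=pd.DataFrame(samples))
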
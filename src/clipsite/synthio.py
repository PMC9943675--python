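"""Synthetic iCLIP/RNA-seq/proteomics data with planted ground truth.

The generator emulates the data shapes the downstream stages consume: a toy
transcriptome with 5'UTR/CDS/3'UTR/intron structure on a single synthetic
chromosome, purine-rich 5-nt motifs planted preferentially in CDS and 3'UTR,
per-replicate crosslink-event tracks with negative-binomial counts (enriched
at planted centers over expression-proportional background), and matched
differential-RNA / protein-LFQ tables with abundance-dependent missing values.

Every artifact draws from its own named RNG substream of the master seed, so
adding an output never perturbs the others, and a fixed config reproduces
byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import formats_io
from .model import CrosslinkTrack, Gene, Transcript, TranscriptAnnotation

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic run (defaults are the conditions)."""

    n_genes: int = 100
    utr5_length: Tuple[int, int] = (50, 200)
    cds_length: Tuple[int, int] = (300, 1200)
    utr3_length: Tuple[int, int] = (150, 600)
    intron_length: Tuple[int, int] = (80, 300)
    intron_prob: float = 0.3
    n_planted_sites_per_gene: Tuple[int, int] = (0, 4)
    region_weights: Dict[str, float] = field(
        default_factory=lambda: {"5UTR": 0.05, "CDS": 0.45, "3UTR": 0.45, "intron": 0.05}
    )
    planted_motif: Optional[str] = "GAAGA"
    motif_alphabet_bias: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.35, "G": 0.35, "C": 0.15, "T": 0.15}
    )
    n_replicates: int = 4
    peak_rate: float = 50.0
    background_rate_per_nt: float = 0.01
    dispersion: Optional[float] = 10.0  # None => Poisson
    u_bias_background: float = 0.0  # optional additive uridine preference
    frac_overlapping_gene_pairs: float = 0.1
    noncoding_fraction: float = 0.05
    multi_transcript_prob: float = 0.3
    expression_sigma: float = 1.0
    de_regulated_fraction: float = 0.3
    de_effect_mean: float = 1.0
    de_effect_sd: float = 0.25
    de_noise: float = 0.1
    prot_detect_fraction: float = 0.85
    prot_regulated_given_rna: float = 0.7
    lfq_base_mean: float = 25.0
    lfq_base_sd: float = 2.0
    lfq_noise: float = 0.3
    lfq_missing_mid: float = 21.0
    lfq_missing_scale: float = 1.0
    pbody_like_fraction: float = 0.2
    dendritic_like_fraction: float = 0.15
    granule_bound_weight: float = 3.0  # bound genes are favored as granule members
    pbody_de_shift: float = 0.4  # upregulation of P-body-like RNAs upon knockdown
    intergenic_gap: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("peak_rate", "background_rate_per_nt", "u_bias_background"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if abs(sum(self.region_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("region_weights must sum to 1")
        for name in ("utr5_length", "cds_length", "utr3_length", "intron_length"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name}: need 0 < lo <= hi, got ({lo}, {hi})")
        if self.cds_length[0] < 30 or self.utr3_length[0] < 30 or self.utr5_length[0] < 30:
            raise ConfigError("region minimum lengths below 30 nt cannot hold planted sites")
        if self.planted_motif is not None and len(self.planted_motif) != 5:
            raise ConfigError("planted_motif must be a 5-mer")
        for frac in (
            self.frac_overlapping_gene_pairs,
            self.noncoding_fraction,
            self.pbody_like_fraction,
            self.dendritic_like_fraction,
            self.de_regulated_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be positive (or None for Poisson)")


@dataclass
class TruthSet:
    """Ground truth recorded alongside each generated artifact."""

    planted_sites: pd.DataFrame  # gene_id, transcript_id, chrom, strand, center, region, motif
    gene_labels: pd.DataFrame  # gene_id, expression, regulated, prot_regulated, pbody_like, dendritic_like
    true_lfq_effects: pd.DataFrame  # protein_id, gene_id, log2_effect

    @property
    def bound_genes(self) -> set:
        return set(self.planted_sites["gene_id"])

    @property
    def validated_targets(self) -> set:
        """Genes bound, RNA-regulated and protein-regulated (the planted triple)."""
        labels = self.gene_labels
        trip = labels[
            (labels["regulated"] != "none") & labels["prot_regulated"]
        ]["gene_id"]
        return set(trip) & self.bound_genes


@dataclass
class OmicsTables:
    rna: pd.DataFrame
    protein: pd.DataFrame
    gene_sets: Dict[str, List[str]]
    dendritic_flags: pd.DataFrame
    pbody_table: pd.DataFrame
    stress_granule_table: pd.DataFrame


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: stable across runs and independent per artifact."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _draw_len(rng: np.random.Generator, bounds: Tuple[int, int]) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def _random_seq(rng: np.random.Generator, n: int, u_bias: float = 0.0) -> str:
    p = np.full(4, 0.25)
    if u_bias > 0:
        p = np.array([0.25 - u_bias / 3, 0.25 - u_bias / 3, 0.25 - u_bias / 3, 0.25 + u_bias])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: Optional[float]
) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion None => Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


# ---------------------------------------------------------------------------
# annotation + genome + truth
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SimConfig,
) -> Tuple[Dict[str, str], TranscriptAnnotation, TruthSet]:
    """Generate genome FASTA sequence, GFF3-expressible annotation and truth.

    Genes are laid out left to right on one synthetic chromosome with a
    designated fraction of overlapping gene pairs; each coding gene carries a
    5'UTR + CDS (+ optional intron) + 3'UTR transcript, optionally a second
    isoform with a truncated 3'UTR. Planted 5-nt motifs are written into the
    genome sequence at the recorded centers.
    """
    config.validate()
    rng = substream(config.seed, "annotation")
    chrom = "chrS"

    ann = TranscriptAnnotation()
    site_rows: List[dict] = []
    label_rows: List[dict] = []
    seq_parts: List[str] = []
    cursor = 100
    seq_parts.append(_random_seq(rng, cursor, config.u_bias_background))

    n_overlap_pairs = int(np.floor(config.frac_overlapping_gene_pairs * config.n_genes))
    overlap_partners = set()
    if n_overlap_pairs > 0 and config.n_genes >= 2:
        step = max(2, config.n_genes // n_overlap_pairs)
        overlap_partners = {i for i in range(1, config.n_genes, step)}
        while len(overlap_partners) > n_overlap_pairs:
            overlap_partners.pop()

    prev_gene: Optional[Gene] = None
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        coding = rng.random() >= config.noncoding_fraction
        overlaps_prev = i in overlap_partners and prev_gene is not None

        if overlaps_prev:
            strand = prev_gene.strand
            level = "3" if rng.random() < 0.5 else "2"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            level = str(rng.choice(["1", "2", "3"], p=[0.5, 0.4, 0.1]))

        # transcript-oriented segment plan: (kind, length)
        if coding:
            segs = [
                ("5UTR", _draw_len(rng, config.utr5_length)),
                ("CDS", _draw_len(rng, config.cds_length)),
                ("3UTR", _draw_len(rng, config.utr3_length)),
            ]
            if rng.random() < config.intron_prob:
                # one intron splitting the CDS roughly in half
                cds_len = segs[1][1]
                left = cds_len // 2
                segs = [
                    segs[0],
                    ("CDS", left),
                    ("intron", _draw_len(rng, config.intron_length)),
                    ("CDS", cds_len - left),
                    segs[2],
                ]
        else:
            segs = [("exon", _draw_len(rng, config.cds_length))]
        gene_len = sum(n for _, n in segs)

        if overlaps_prev:
            shift = min(50, prev_gene.end - prev_gene.start - 10)
            start = prev_gene.end - shift
            cursor = max(cursor, start + gene_len)
            # extend sequence if the overlapping gene runs past what is drawn
            needed = start + gene_len - sum(len(s) for s in seq_parts)
            if needed > 0:
                seq_parts.append(_random_seq(rng, needed, config.u_bias_background))
        else:
            start = cursor + config.intergenic_gap
            seq_parts.append(
                _random_seq(
                    rng,
                    start + gene_len - sum(len(s) for s in seq_parts),
                    config.u_bias_background,
                )
            )
            cursor = start + gene_len

        gene = Gene(
            id=gid,
            chrom=chrom,
            start=start,
            end=start + gene_len,
            strand=strand,
            level=level,
            biotype="protein_coding" if coding else "lncRNA",
        )

        # genomic placement: transcript order for "+", reversed for "-"
        placed = segs if strand == "+" else list(reversed(segs))
        pos = start
        genomic_segs: List[Tuple[str, int, int]] = []
        for kind, n in placed:
            genomic_segs.append((kind, pos, pos + n))
            pos += n

        def build_tx(tid: str, tlevel: str, trunc_3utr: int = 0) -> Transcript:
            tx = Transcript(id=tid, gene_id=gid, chrom=chrom, strand=strand, level=tlevel)
            for kind, s, e in genomic_segs:
                if kind == "intron":
                    continue
                if kind == "3UTR" and trunc_3utr:
                    if strand == "+":
                        e = max(s + 10, e - trunc_3utr)
                    else:
                        s = min(e - 10, s + trunc_3utr)
                if kind == "exon":
                    tx.exons.append((s, e))
                    continue
                getattr(tx, {"5UTR": "utr5", "CDS": "cds", "3UTR": "utr3"}[kind]).append((s, e))
                tx.exons.append((s, e))
            # merge adjacent exon pieces so introns are exactly the gaps
            tx.exons = _merge_adjacent(sorted(tx.exons))
            tx.cds.sort(); tx.utr5.sort(); tx.utr3.sort()
            return tx

        tx1 = build_tx(f"{gid}.t1", "1" if level in ("1", "2") else "2")
        gene.transcripts[tx1.id] = tx1
        if coding and rng.random() < config.multi_transcript_prob:
            utr3_len = sum(e - s for s, e in tx1.utr3)
            tlevel = "NA" if rng.random() < 0.3 else "2"
            tx2 = build_tx(f"{gid}.t2", tlevel, trunc_3utr=utr3_len // 2)
            gene.transcripts[tx2.id] = tx2

        ann.genes[gid] = gene

        # planted sites
        n_sites = int(
            rng.integers(
                config.n_planted_sites_per_gene[0], config.n_planted_sites_per_gene[1] + 1
            )
        )
        weights = dict(config.region_weights)
        has_intron = any(k == "intron" for k, *_ in genomic_segs)
        if not coding:
            region_pool = {"noncoding": 1.0}
        else:
            if not has_intron:
                weights.pop("intron", None)
            tot = sum(weights.values())
            region_pool = {k: v / tot for k, v in weights.items()}

        taken: List[int] = []
        for _ in range(n_sites):
            region = str(
                rng.choice(list(region_pool), p=np.array(list(region_pool.values())))
            )
            kind = "exon" if region == "noncoding" else region
            choices = [(s, e) for k, s, e in genomic_segs if k == kind]
            s, e = choices[int(rng.integers(len(choices)))]
            margin = min(35, (e - s) // 3)
            for _attempt in range(20):
                center = int(rng.integers(s + margin, e - margin))
                if all(abs(center - t) >= 12 for t in taken):
                    break
            else:
                continue
            taken.append(center)
            if config.planted_motif is not None:
                motif = config.planted_motif
            else:
                bias = config.motif_alphabet_bias
                motif = "".join(
                    rng.choice(list("AGCT"), p=[bias["A"], bias["G"], bias["C"], bias["T"]])
                    for _ in range(5)
                )
            site_rows.append(
                dict(
                    gene_id=gid,
                    transcript_id=tx1.id,
                    chrom=chrom,
                    strand=strand,
                    center=center,
                    region=region,
                    motif=motif,
                )
            )

        label_rows.append(dict(gene_id=gid, coding=coding))
        prev_gene = gene

    genome_seq = "".join(seq_parts)
    genome_seq += _random_seq(rng, 300, config.u_bias_background)  # tail margin
    genome = {chrom: genome_seq}
    ann.chrom_lengths[chrom] = len(genome_seq)

    # write planted motifs into the genome (transcript orientation)
    seq = list(genome_seq)
    for row in site_rows:
        motif = row["motif"]
        if row["strand"] == "-":
            motif = motif.translate(COMPLEMENT)[::-1]
        c = row["center"]
        seq[c - 2 : c + 3] = list(motif)
    genome[chrom] = "".join(seq)

    # gene-level labels: expression, DE regulation, protein regulation, set labels
    lrng = substream(config.seed, "labels")
    labels = pd.DataFrame(label_rows)
    n = len(labels)
    labels["expression"] = np.exp(lrng.normal(0.0, config.expression_sigma, size=n))
    reg = np.array(["none"] * n, dtype=object)
    n_reg = int(round(config.de_regulated_fraction * n))
    reg_idx = lrng.choice(n, size=n_reg, replace=False)
    reg[reg_idx] = np.where(lrng.random(n_reg) < 0.5, "up", "down")
    labels["regulated"] = reg
    prot_reg = np.zeros(n, dtype=bool)
    prot_reg[reg_idx] = lrng.random(n_reg) < config.prot_regulated_given_rna
    extra = lrng.choice(n, size=max(1, n // 20), replace=False)
    prot_reg[extra] |= lrng.random(len(extra)) < 0.5
    labels["prot_regulated"] = prot_reg
    # granule membership is drawn with a weight toward bound genes, emulating
    # the observed binding/granule-transcriptome association
    bound_ids = {r["gene_id"] for r in site_rows}
    weights = np.where(
        labels["gene_id"].isin(bound_ids), config.granule_bound_weight, 1.0
    )
    weights = weights / weights.sum()
    n_pbody = int(np.floor(config.pbody_like_fraction * n))
    pbody = np.zeros(n, dtype=bool)
    if n_pbody:
        pbody[lrng.choice(n, size=n_pbody, replace=False, p=weights)] = True
    labels["pbody_like"] = pbody
    n_dend = int(np.floor(config.dendritic_like_fraction * n))
    dend = np.zeros(n, dtype=bool)
    if n_dend:
        dend[lrng.choice(n, size=n_dend, replace=False, p=weights)] = True
    labels["dendritic_like"] = dend

    truth = TruthSet(
        planted_sites=pd.DataFrame(
            site_rows,
            columns=["gene_id", "transcript_id", "chrom", "strand", "center", "region", "motif"],
        ),
        gene_labels=labels,
        true_lfq_effects=pd.DataFrame(columns=["protein_id", "gene_id", "log2_effect"]),
    )
    return genome, ann, truth


def _merge_adjacent(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# crosslink tracks
# ---------------------------------------------------------------------------

def simulate_crosslinks(
    ann: TranscriptAnnotation, truth: TruthSet, config: SimConfig
) -> List[CrosslinkTrack]:
    """Per-replicate crosslink-event tracks on the transcribed strand.

    Background counts are NB with mean ``background_rate_per_nt * expression``
    per transcribed nucleotide; planted centers get mean ``peak_rate`` with a
    decaying shoulder at +-1/+-2 nt so the center is the crosslink maximum.
    """
    config.validate()
    expr = dict(zip(truth.gene_labels["gene_id"], truth.gene_labels["expression"]))
    sites_by_gene: Dict[str, List[int]] = {}
    for row in truth.planted_sites.itertuples():
        sites_by_gene.setdefault(row.gene_id, []).append(row.center)

    tracks: List[CrosslinkTrack] = []
    shoulder = {0: 1.0, 1: 0.4, -1: 0.4, 2: 0.15, -2: 0.15}
    for r in range(1, config.n_replicates + 1):
        rng = substream(config.seed, f"crosslinks/rep{r}")
        track = CrosslinkTrack(label=f"rep{r}")
        for gid in sorted(ann.genes):
            gene = ann.genes[gid]
            mu = np.full(gene.end - gene.start, config.background_rate_per_nt * expr[gid])
            for center in sites_by_gene.get(gid, []):
                for off, w in shoulder.items():
                    idx = center + off - gene.start
                    if 0 <= idx < len(mu):
                        mu[idx] += config.peak_rate * w
            counts = _negative_binomial(rng, mu, config.dispersion)
            for idx in np.nonzero(counts)[0]:
                track.add(gene.chrom, gene.strand, gene.start + int(idx), int(counts[idx]))
        tracks.append(track)
    return tracks


# ---------------------------------------------------------------------------
# omics tables
# ---------------------------------------------------------------------------

def simulate_omics_tables(truth: TruthSet, config: SimConfig) -> OmicsTables:
    """Differential-RNA table, 4v4 LFQ matrix, gene sets and published-style tables."""
    config.validate()
    labels = truth.gene_labels.set_index("gene_id", drop=False)
    genes = list(labels["gene_id"])

    # --- RNA differential expression ------------------------------------
    rng = substream(config.seed, "rna_de")
    rows = []
    for gid in genes:
        lab = labels.loc[gid]
        base_mean = 1000.0 * lab["expression"]
        if lab["regulated"] != "none":
            sign = 1.0 if lab["regulated"] == "up" else -1.0
            l2fc = sign * abs(rng.normal(config.de_effect_mean, config.de_effect_sd))
            l2fc += rng.normal(0.0, config.de_noise)
            padj = 10.0 ** -rng.uniform(3, 8)
        else:
            l2fc = rng.normal(0.0, 0.15)
            padj = rng.uniform(0.02, 1.0)
        if lab["pbody_like"]:
            l2fc += config.pbody_de_shift
        rows.append(dict(gene_id=gid, baseMean=base_mean, log2FoldChange=l2fc, padj=padj))
    rna = pd.DataFrame(rows)

    # --- protein LFQ 4v4 -------------------------------------------------
    prng = substream(config.seed, "lfq")
    prot_rows = []
    effect_rows = []
    for gid in genes:
        lab = labels.loc[gid]
        if not lab["coding"] or prng.random() > config.prot_detect_fraction:
            continue
        pid = f"P_{gid}"
        if lab["prot_regulated"]:
            sign = 1.0 if lab["regulated"] == "up" else -1.0
            if lab["regulated"] == "none":
                sign = 1.0 if prng.random() < 0.5 else -1.0
            effect = sign * abs(prng.normal(config.de_effect_mean, config.de_effect_sd))
            padj = prng.uniform(1e-6, 0.01)
        else:
            effect = 0.0
            padj = prng.uniform(0.06, 1.0)
        base = prng.normal(config.lfq_base_mean, config.lfq_base_sd)
        row = dict(protein_id=pid, gene_id=gid)
        for cond, shift, tag in (("KD", effect, "KD"), ("CTRL", 0.0, "CTRL")):
            for k in range(1, 5):
                x = base + shift + prng.normal(0.0, config.lfq_noise)
                p_miss = 1.0 / (1.0 + np.exp((x - config.lfq_missing_mid) / config.lfq_missing_scale))
                row[f"{tag}{k}"] = np.nan if prng.random() < p_miss else round(x, 4)
        row["padj"] = padj
        prot_rows.append(row)
        effect_rows.append(dict(protein_id=pid, gene_id=gid, log2_effect=effect))
    protein = pd.DataFrame(
        prot_rows,
        columns=["protein_id", "gene_id"]
        + [f"KD{k}" for k in range(1, 5)]
        + [f"CTRL{k}" for k in range(1, 5)]
        + ["padj"],
    )
    truth.true_lfq_effects = pd.DataFrame(
        effect_rows, columns=["protein_id", "gene_id", "log2_effect"]
    )

    # --- gene sets --------------------------------------------------------
    grng = substream(config.seed, "gene_sets")
    gene_sets: Dict[str, List[str]] = {
        "PBODY_LIKE": sorted(labels.loc[labels["pbody_like"], "gene_id"]),
        "DENDRITIC_LIKE": sorted(labels.loc[labels["dendritic_like"], "gene_id"]),
    }
    for t in range(8):
        size = int(grng.integers(10, max(11, len(genes) // 2)))
        members = grng.choice(genes, size=min(size, len(genes)), replace=False)
        gene_sets[f"RANDOM_TERM_{t:02d}"] = sorted(members)

    # --- dendritic per-study enrichment flags ----------------------------
    drng = substream(config.seed, "dendritic")
    flag_rows = []
    for gid in genes:
        k = int(drng.integers(3, 9)) if labels.loc[gid, "dendritic_like"] else int(drng.integers(0, 3))
        flags = np.zeros(8, dtype=int)
        flags[drng.choice(8, size=k, replace=False)] = 1
        flag_rows.append(dict(gene_id=gid, **{f"study{j+1}": int(f) for j, f in enumerate(flags)}))
    dendritic_flags = pd.DataFrame(flag_rows)

    # --- published-style granule transcriptome tables ---------------------
    def granule_table(col: str, stream: str) -> pd.DataFrame:
        trng = substream(config.seed, stream)
        out = []
        for gid in genes:
            if labels.loc[gid, col]:
                out.append(dict(gene_id=gid, l2fc=abs(trng.normal(1.0, 0.3)), FDR=10.0 ** -trng.uniform(3, 8)))
            else:
                out.append(dict(gene_id=gid, l2fc=trng.normal(0.0, 0.3), FDR=trng.uniform(0.05, 1.0)))
        return pd.DataFrame(out)

    pbody_table = granule_table("pbody_like", "pbody_table")
    sg_table = granule_table("dendritic_like", "sg_table")

    return OmicsTables(
        rna=rna,
        protein=protein,
        gene_sets=gene_sets,
        dendritic_flags=dendritic_flags,
        pbody_table=pbody_table,
        stress_granule_table=sg_table,
    )


# ---------------------------------------------------------------------------
# one-call generation + writers
# ---------------------------------------------------------------------------

def generate_all(config: SimConfig):
    genome, ann, truth = generate_annotation(config)
    tracks = simulate_crosslinks(ann, truth, config)
    omics = simulate_omics_tables(truth, config)
    return genome, ann, truth, tracks, omics


def write_all(outdir, genome, ann, truth, tracks, omics) -> Dict[str, str]:
    """Write every artifact as plain text; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    formats_io.write_fasta(genome, outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    formats_io.write_gff3(ann, outdir / "annotation.gff3")
    paths["annotation"] = str(outdir / "annotation.gff3")
    for track in tracks:
        plus = outdir / f"{track.label}.plus.bedgraph"
        minus = outdir / f"{track.label}.minus.bedgraph"
        formats_io.write_bedgraph_pair(track, plus, minus)
        paths[track.label] = str(plus)
    formats_io.write_tsv(truth.planted_sites, outdir / "truth_sites.tsv")
    formats_io.write_tsv(truth.gene_labels, outdir / "truth_gene_labels.tsv")
    formats_io.write_tsv(truth.true_lfq_effects, outdir / "truth_lfq_effects.tsv")
    formats_io.write_tsv(omics.rna, outdir / "de.tsv")
    formats_io.write_tsv(omics.protein, outdir / "lfq.tsv")
    formats_io.write_gmt(omics.gene_sets, outdir / "gene_sets.gmt")
    formats_io.write_tsv(omics.dendritic_flags, outdir / "dendritic_flags.tsv")
    formats_io.write_tsv(omics.pbody_table, outdir / "pbody_published.tsv")
    formats_io.write_tsv(omics.stress_granule_table, outdir / "sg_published.tsv")
    for name in (
        "truth_sites", "truth_gene_labels", "truth_lfq_effects", "de", "lfq",
        "gene_sets", "dendritic_flags", "pbody_published", "sg_published",
    ):
        suffix = ".gmt" if name == "gene_sets" else ".tsv"
        paths[name] = str(outdir / f"{name}{suffix}")
    return paths
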
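"""End-to-end pipeline stages over files, shared by the CLI and `run_all`.

Every stage consumes and produces plain-text artifacts (FASTA/GFF3/bedGraph/
BED6/TSV/GMT) so runs are inspectable and reruns with the same master seed
are byte-identical. Each randomized stage draws from a named substream of
the master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import access as access_mod
from . import formats_io, integrate, profiles, seqmotif, sitecall, synthio, txassign
from .model import BindingSite, CrosslinkTrack, GenomicInterval, TranscriptAnnotation
from .synthio import SimConfig, substream


@dataclass
class PipelineConfig:
    """One config object for the synthetic end-to-end run."""

    outdir: str = "clipsite_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    sitecall: sitecall.SiteCallParams = field(default_factory=sitecall.SiteCallParams)
    access: access_mod.AccessParams = field(
        default_factory=lambda: access_mod.AccessParams(
            window=201, display_center=101, n_regions_per_draw=200, n_draws=200
        )
    )
    profile: profiles.ProfileParams = field(default_factory=profiles.ProfileParams)
    rna_padj: float = integrate.RNA_PADJ_THRESHOLD
    protein_padj: float = integrate.PROTEIN_PADJ_THRESHOLD
    published_fdr: float = integrate.PUBLISHED_FDR_THRESHOLD
    n_background_pool: int = 600

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.access.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            outdir=raw.get("outdir", "clipsite_run"),
            seed=int(raw.get("seed", 0)),
        )
        for section, target in (
            ("sim", cfg.sim),
            ("sitecall", cfg.sitecall),
            ("access", cfg.access),
            ("profile", cfg.profile),
        ):
            for key, value in (raw.get(section) or {}).items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown {section} option {key!r}")
                setattr(target, key, value)
        for key in ("rna_padj", "protein_padj", "published_fdr", "n_background_pool"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.sim.seed = cfg.seed
        cfg.access.seed = cfg.seed
        return cfg


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _tx_sequences(ann: TranscriptAnnotation, genome: Dict[str, str]) -> Dict[str, str]:
    return {tx.id: tx.spliced_sequence(genome) for tx in ann.transcripts()}


def crosslinked_transcripts(
    ann: TranscriptAnnotation, tracks: Sequence[CrosslinkTrack]
) -> List[str]:
    """Transcripts of genes harboring at least one crosslink event."""
    out = []
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        total = sum(t.window_sum(g.chrom, g.strand, g.start, g.end) for t in tracks)
        if total > 0:
            out.extend(sorted(g.transcripts))
    return out


def _read_tracks(paths: Sequence[Tuple[str, str]]) -> List[CrosslinkTrack]:
    return [
        formats_io.read_bedgraph_pair(p, m, label=f"rep{i+1}")
        for i, (p, m) in enumerate(paths)
    ]


def _track_paths(simdir: Path, n: int) -> List[Tuple[str, str]]:
    return [
        (str(simdir / f"rep{i}.plus.bedgraph"), str(simdir / f"rep{i}.minus.bedgraph"))
        for i in range(1, n + 1)
    ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Dict[str, str]:
    simdir = Path(cfg.outdir) / "sim"
    genome, ann, truth, tracks, omics = synthio.generate_all(cfg.sim)
    return synthio.write_all(simdir, genome, ann, truth, tracks, omics)


def stage_callsites(
    cfg: PipelineConfig, candidates_bed: Optional[str] = None
) -> Tuple[List[BindingSite], sitecall.SiteCallLog]:
    simdir = Path(cfg.outdir) / "sim"
    tracks = _read_tracks(_track_paths(simdir, cfg.sim.n_replicates))
    candidates = (
        formats_io.read_candidates_bed(candidates_bed) if candidates_bed else None
    )
    sites, log = sitecall.call_binding_sites(tracks, cfg.sitecall, candidates)
    outdir = Path(cfg.outdir)
    formats_io.write_binding_sites_bed(sites, outdir / "sites.bed")
    (outdir / "sitecall_log.json").write_text(json.dumps(log.as_dict(), indent=2, sort_keys=True))
    return sites, log


def stage_annotate(cfg: PipelineConfig, sites: Sequence[BindingSite]) -> txassign.AssignmentResult:
    outdir = Path(cfg.outdir)
    simdir = outdir / "sim"
    ann = formats_io.read_gff3(simdir / "annotation.gff3")
    tracks = _read_tracks(_track_paths(simdir, cfg.sim.n_replicates))
    seed = int(substream(cfg.seed, "assign").integers(2**31))
    result = txassign.assign_sites(sites, ann, tracks, seed=seed)
    formats_io.write_tsv(result.table, outdir / "assigned.tsv")
    groups = pd.DataFrame(
        sorted(result.groups.items()), columns=["transcript_id", "group"]
    )
    formats_io.write_tsv(groups, outdir / "strongest_site_groups.tsv")
    density = txassign.sites_per_region_normalized(result.table, ann, tracks)
    formats_io.write_tsv(density, outdir / "region_density.tsv")
    return result


def stage_motif(cfg: PipelineConfig, assigned: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    outdir = Path(cfg.outdir)
    simdir = outdir / "sim"
    ann = formats_io.read_gff3(simdir / "annotation.gff3")
    genome = formats_io.read_fasta(simdir / "genome.fa")
    tracks = _read_tracks(_track_paths(simdir, cfg.sim.n_replicates))
    tx_seqs = _tx_sequences(ann, genome)

    mapped = assigned[assigned["tx_pos"] >= 0]
    tx_positions = list(zip(mapped["transcript_id"], mapped["tx_pos"]))

    fg = {}
    for name in ("center", "upstream", "downstream"):
        fg[name], _ = seqmotif.extract_windows(tx_positions, tx_seqs, seqmotif.WINDOWS[name])
    logo_windows, _ = seqmotif.extract_windows(tx_positions, tx_seqs, seqmotif.WINDOWS["logo"])
    site_seqs, _ = seqmotif.extract_windows(tx_positions, tx_seqs, seqmotif.WINDOWS["site"])

    rng = substream(cfg.seed, "motif_background")
    eligible = crosslinked_transcripts(ann, tracks)
    bg, _pos = seqmotif.sample_background(tx_seqs, eligible, max(len(site_seqs), 1), 15, rng)
    kmers = seqmotif.kmer_enrichment(fg, bg, k=5)
    logo = seqmotif.logo_matrix(logo_windows) if logo_windows else pd.DataFrame()
    stats = seqmotif.purine_stats(site_seqs) if site_seqs else pd.DataFrame()

    formats_io.write_tsv(kmers.table, outdir / "motif_kmers.tsv")
    if not logo.empty:
        formats_io.write_tsv(logo, outdir / "logo_matrix.tsv")
        formats_io.write_tsv(seqmotif.logo_display_slice(logo), outdir / "logo_matrix_21nt.tsv")
    if not stats.empty:
        formats_io.write_tsv(stats, outdir / "purine_stats.tsv")
    return {"kmers": kmers.table, "logo": logo, "purine": stats}


def stage_access(cfg: PipelineConfig, assigned: pd.DataFrame, backend: str = "toy"):
    outdir = Path(cfg.outdir)
    simdir = outdir / "sim"
    ann = formats_io.read_gff3(simdir / "annotation.gff3")
    genome = formats_io.read_fasta(simdir / "genome.fa")
    tracks = _read_tracks(_track_paths(simdir, cfg.sim.n_replicates))
    tx_seqs = _tx_sequences(ann, genome)
    params = cfg.access
    half = params.window // 2

    mapped = assigned[assigned["tx_pos"] >= 0]
    fg_seqs, _ = seqmotif.extract_windows(
        list(zip(mapped["transcript_id"], mapped["tx_pos"])), tx_seqs, (-half, half)
    )
    if not fg_seqs:
        raise ValueError("no binding-site window fits inside a transcript")
    rng = substream(cfg.seed, "access_background")
    eligible = crosslinked_transcripts(ann, tracks)
    bg_seqs, _ = seqmotif.sample_background(
        tx_seqs, eligible, cfg.n_background_pool, params.window, rng
    )
    fg = access_mod.window_logodds(fg_seqs, params, backend)
    bg = access_mod.window_logodds(bg_seqs, params, backend)
    zrng = substream(cfg.seed, "access_draws")
    profile = access_mod.accessibility_zscore(fg, bg, params, zrng)
    formats_io.write_tsv(profile.table, outdir / "access.tsv")
    return profile


def stage_profile(cfg: PipelineConfig, sites: Sequence[BindingSite], result: txassign.AssignmentResult):
    outdir = Path(cfg.outdir)
    simdir = outdir / "sim"
    ann = formats_io.read_gff3(simdir / "annotation.gff3")
    tracks = _read_tracks(_track_paths(simdir, cfg.sim.n_replicates))
    merged = tracks[0]
    for t in tracks[1:]:
        merged = merged.merge(t, label="merged")
    params = cfg.profile

    kept = txassign.filter_genes_by_level(ann)
    utr3_regions, utr3_ids = [], []
    region_by_group: Dict[str, List[GenomicInterval]] = {"3UTR": [], "CDS": []}
    for gid in sorted(kept.genes):
        gene = kept.genes[gid]
        tx = txassign.canonical_transcript(gene)
        if tx is None or not tx.utr3:
            continue
        s = min(a for a, _ in tx.utr3)
        e = max(b for _, b in tx.utr3)
        iv = GenomicInterval(gene.chrom, s, e, gene.strand)
        utr3_regions.append(iv)
        utr3_ids.append(tx.id)
        group = result.groups.get(tx.id)
        if group == "3UTR":
            region_by_group["3UTR"].append(iv)
        elif group == "CDS" and tx.cds:
            cs = min(a for a, _ in tx.cds)
            ce = max(b for _, b in tx.cds)
            region_by_group["CDS"].append(GenomicInterval(gene.chrom, cs, ce, gene.strand))

    heatmap, kept_ids = profiles.region_window_heatmap(merged, utr3_regions, params, utr3_ids)
    meta, matrix, skipped = profiles.site_metaprofile(merged, sites, params)
    kde = profiles.scaled_region_metaprofile(merged, region_by_group)

    hm = pd.DataFrame(heatmap, columns=[f"c{i}" for i in range(heatmap.shape[1])])
    hm.insert(0, "transcript_id", kept_ids)
    formats_io.write_tsv(hm, outdir / "utr3_heatmap.tsv")
    half = params.site_window // 2
    formats_io.write_tsv(
        pd.DataFrame({"rel_pos": np.arange(-half, half + 1), "mean_signal": meta}),
        outdir / "site_metaprofile.tsv",
    )
    for group, df in kde.items():
        formats_io.write_tsv(df, outdir / f"scaled_metaprofile_{group}.tsv")
    return {"heatmap_rows": len(kept_ids), "metaprofile_sites": matrix.shape[0], "skipped_sites": skipped}


def stage_integrate(cfg: PipelineConfig, assigned: pd.DataFrame) -> Dict[str, object]:
    outdir = Path(cfg.outdir)
    simdir = outdir / "sim"
    rna = formats_io.read_tsv(simdir / "de.tsv")
    lfq = formats_io.read_tsv(simdir / "lfq.tsv")
    gene_sets = formats_io.read_gmt(simdir / "gene_sets.gmt")
    pbody = formats_io.read_tsv(simdir / "pbody_published.tsv")
    sg = formats_io.read_tsv(simdir / "sg_published.tsv")
    dendritic = formats_io.read_tsv(simdir / "dendritic_flags.tsv")

    prot = integrate.proteomics_ratios(lfq, log2_transform=False)
    formats_io.write_tsv(prot, outdir / "protein_ratios.tsv")

    bound = sorted(set(assigned["gene_id"]))
    sets = integrate.build_sets(
        rna, prot, bound, rna_threshold=cfg.rna_padj, protein_threshold=cfg.protein_padj
    )
    sets_df = pd.DataFrame(
        [
            dict(set="rna_significant", n=len(sets.rna_significant)),
            dict(set="protein_significant", n=len(sets.protein_significant)),
            dict(set="bound", n=len(sets.bound)),
            dict(set="rna_and_protein", n=len(sets.rna_and_protein)),
            dict(set="validated", n=len(sets.validated)),
            dict(set="validated_concordant", n=len(sets.validated_concordant)),
        ]
    )
    formats_io.write_tsv(sets_df, outdir / "target_sets.tsv")
    formats_io.write_tsv(
        pd.DataFrame({"gene_id": sorted(sets.validated)}), outdir / "validated_targets.tsv"
    )

    universe = set(rna.loc[rna["baseMean"] > 0, "gene_id"])
    pbody_set = integrate.published_membership(pbody, cfg.published_fdr)
    sg_set = integrate.published_membership(sg, cfg.published_fdr)
    overlaps = []
    for name, other in (("pbody", pbody_set), ("stress_granule", sg_set)):
        res = integrate.overlap_test(set(bound), other, universe)
        frac = len(set(bound) & other) / len(other & universe) if other & universe else float("nan")
        overlaps.append(
            dict(
                comparison=name,
                n_other=len(other & universe),
                n_overlap=res.table[0][0],
                bound_fraction_of_other=frac,
                odds_ratio=res.odds_ratio,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p_value,
            )
        )
    overlap_df = pd.DataFrame(overlaps)
    formats_io.write_tsv(overlap_df, outdir / "overlap_tests.tsv")

    rna_idx = rna.set_index("gene_id")
    in_pbody = rna_idx.loc[rna_idx.index.isin(pbody_set), "log2FoldChange"]
    rest = rna_idx.loc[~rna_idx.index.isin(pbody_set), "log2FoldChange"]
    shift_p, shift_median = integrate.shift_test(in_pbody, rest)

    dend = integrate.dendritic_consensus(dendritic, min_studies=3, expressed=universe)
    dend_overlap = len(dend & set(bound))

    enrich = integrate.hypergeom_enrichment(set(bound), gene_sets, set(rna["gene_id"]))
    formats_io.write_tsv(integrate.top_terms(enrich), outdir / "enrichment.tsv")

    heat = None
    validated = sorted(sets.validated)
    prot_idx = prot.set_index("gene_id")
    rows = [g for g in validated if g in prot_idx.index]
    if rows:
        mat = prot_idx.loc[rows, integrate.KD_COLS + integrate.CTRL_COLS].dropna()
        if len(mat) >= 1 and mat.shape[1] >= 2:
            heat = integrate.zscore_rows(mat)
            heat_out = heat.reset_index()
            formats_io.write_tsv(heat_out, outdir / "validated_heatmap_z.tsv")

    return {
        "sets": sets,
        "overlaps": overlap_df,
        "pbody_shift_p": shift_p,
        "pbody_shift_median": shift_median,
        "dendritic_consensus_n": len(dend),
        "dendritic_bound_overlap": dend_overlap,
        "enrichment": enrich,
    }


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig) -> Dict[str, object]:
    """Execute every stage and write a JSON run report; returns the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"seed": cfg.seed, "stages": {}}
    stages = report["stages"]  # type: ignore[assignment]

    stage_simulate(cfg)
    truth_sites = formats_io.read_tsv(outdir / "sim" / "truth_sites.tsv")
    stages["simulate"] = {"n_genes": cfg.sim.n_genes, "n_planted_sites": len(truth_sites)}

    sites, log = stage_callsites(cfg)
    stages["callsites"] = log.as_dict()

    result = stage_annotate(cfg, sites)
    stages["annotate"] = {
        "n_assigned": len(result.table),
        "n_unassigned": result.n_unassigned,
        "n_junction_dropped": result.n_junction_dropped,
    }

    motif_out = stage_motif(cfg, result.table)
    stages["motif"] = {"n_kmers": len(motif_out["kmers"])}

    profile_acc = stage_access(cfg, result.table)
    central = profile_acc.table.loc[profile_acc.table["rel_pos"].abs() <= 2, "z"]
    stages["access"] = {
        "n_foreground": profile_acc.n_foreground,
        "central_z_mean": float(central.mean()),
    }

    stages["profile"] = stage_profile(cfg, sites, result)

    integ = stage_integrate(cfg, result.table)
    sets = integ["sets"]
    stages["integrate"] = {
        "n_rna_significant": len(sets.rna_significant),
        "n_protein_significant": len(sets.protein_significant),
        "n_bound": len(sets.bound),
        "n_validated": len(sets.validated),
        "pbody_shift_p": integ["pbody_shift_p"],
    }

    from . import __version__

    report["version"] = __version__
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
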
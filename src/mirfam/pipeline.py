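"""End-to-end orchestration: discovery -> validation -> clustering -> targets -> trees.

A single :class:`PipelineConfig` drives the whole annotation workflow over
either real FASTA inputs or a synthetic specification, writing one run
directory of TSV/FASTA/Newick/JSON artifacts.  Every artifact carries a
provenance header (config hash and seed) and two runs with the same config
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import hairpin, homology_scan, mature_clustering, phylo, synthetic_data, target_scoring
from .homology_scan import ConfigurationError
from .seqio import MatureMiRNA, SequenceRecord, read_fasta, write_fasta
from .target_scoring import PenaltyScheme

logger = logging.getLogger("mirfam")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    # inputs: either FASTA paths or a synthetic spec
    query_fasta: Path | None = None
    subject_fasta: Path | None = None
    transcript_fasta: Path | None = None
    synthetic: synthetic_data.SyntheticSpec | None = None
    # stage parameters (defaults mirror the published settings)
    max_mismatches: int = 0
    flank_up: int = homology_scan.DEFAULT_FLANK
    flank_down: int = homology_scan.DEFAULT_FLANK
    max_window: int = homology_scan.DEFAULT_MAX_WINDOW
    min_loop: int = hairpin.MIN_LOOP_DEFAULT
    energy_cutoff: float = hairpin.ENERGY_CUTOFF_DEFAULT
    min_mature_paired: int = hairpin.MIN_MATURE_PAIRED
    bracket_tolerance: int = 0
    scheme: PenaltyScheme = field(default_factory=PenaltyScheme)
    bootstrap: int = 1000
    mature_len_hint: int = 20

    def validate(self) -> None:
        if self.flank_up + self.mature_len_hint + self.flank_down > self.max_window:
            raise ConfigurationError(
                f"flank_up + mature + flank_down = "
                f"{self.flank_up + self.mature_len_hint + self.flank_down} exceeds "
                f"max_window={self.max_window}"
            )
        if self.max_mismatches < 0 or self.bootstrap < 1 or self.bracket_tolerance < 0:
            raise ConfigurationError("parameter out of range")
        if self.synthetic is None and (self.query_fasta is None or self.subject_fasta is None):
            raise ConfigurationError("need either a synthetic spec or query+subject FASTA")

    def config_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "out_dir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path, out_dir: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        syn = raw.pop("synthetic", None)
        scheme = raw.pop("scheme", None)
        for key in ("query_fasta", "subject_fasta", "transcript_fasta"):
            if key in raw:
                raw[key] = Path(raw[key])
        cfg = cls(out_dir=Path(out_dir), **raw)
        if syn is not None:
            if "transcript_specs" in syn:
                syn["transcript_specs"] = tuple(
                    (int(length), tuple(synthetic_data.Edit(k, int(p)) for k, p in edits))
                    for length, edits in syn["transcript_specs"]
                )
            cfg.synthetic = synthetic_data.SyntheticSpec(**syn)
        if scheme is not None:
            cfg.scheme = PenaltyScheme(**scheme)
        return cfg


def _header(cfg: PipelineConfig) -> str:
    return f"# mirfam run config={cfg.config_hash()} seed={cfg.seed}\n"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write reports into ``cfg.out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Any stage error aborts with the stage name attached.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    stage = "inputs"
    try:
        # ------------------------------------------------------------------ inputs
        if cfg.synthetic is not None:
            spec = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            genome, truth = synthetic_data.synthesize_genome(spec)
            transcripts, t_truth = synthetic_data.synthesize_transcripts(spec, cfg.scheme)
            family, f_truth = synthetic_data.simulate_family(spec)
            queries = [MatureMiRNA(id="query-mir", sequence=spec.mature_seq)]
            subjects = [genome]
            write_fasta(subjects, out / "subjects.fasta")
            write_fasta(transcripts, out / "transcripts.fasta")
            manifest = {
                "implants": truth.implants,
                "decoys": truth.decoys,
                "transcript_sites": t_truth.transcript_sites,
                "family_tree": f_truth.family_tree,
                "leaf_sequences": f_truth.leaf_sequences,
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        else:
            queries = [
                MatureMiRNA(id=r.id, sequence=r.sequence)
                for r in read_fasta(cfg.query_fasta)
            ]
            subjects = read_fasta(cfg.subject_fasta)
            transcripts = (
                read_fasta(cfg.transcript_fasta) if cfg.transcript_fasta else []
            )
            family = None
        summary["stages"]["queries"] = len(queries)
        summary["stages"]["subjects"] = len(subjects)

        # ------------------------------------------------------------------ scan
        stage = "scan"
        hits = []
        for q in queries:
            for s in subjects:
                for h in homology_scan.scan_for_mature(q, s, cfg.max_mismatches):
                    hits.append((q, s, h))
        with open(out / "hits.tsv", "w") as fh:
            fh.write(_header(cfg))
            fh.write("query\tsubject\tstart\tend\tstrand\tmismatches\n")
            for q, s, h in hits:
                fh.write(f"{q.id}\t{h.subject_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.mismatches}\n")
        summary["stages"]["hits"] = len(hits)

        # ----------------------------------------------- window + screen + fold
        stage = "window/screen/fold/validate"
        validated = []
        windows = []
        with open(out / "hairpin_report.tsv", "w") as fh:
            fh.write(_header(cfg))
            fh.write(
                "query\twindow\tscreen\tmature_paired\tcentral_loop\tsingle_stem\t"
                "energy\tverdict\treasons\n"
            )
            for q, s, h in hits:
                w = homology_scan.extract_precursor_window(
                    h, s, cfg.flank_up, cfg.flank_down, cfg.max_window
                )
                screen = homology_scan.screen_candidate(w)
                if not screen.passed:
                    fh.write(
                        f"{q.id}\t{w.provenance}\tfail:{','.join(screen.reasons)}"
                        f"\t\t\t\t\tFALSE\tscreened_out\n"
                    )
                    continue
                report, sub = hairpin.best_precursor_report(
                    w,
                    energy_cutoff=cfg.energy_cutoff,
                    min_mature_paired=cfg.min_mature_paired,
                    min_loop=cfg.min_loop,
                )
                windows.append((q, w, sub, report))
                fh.write(
                    f"{q.id}\t{sub.provenance}\tpass\t{report.mature_paired}\t"
                    f"{report.has_central_loop}\t{report.single_stem}\t"
                    f"{report.energy_estimate:.1f}\t{report.verdict}\t"
                    f"{';'.join(report.reasons)}\n"
                )
                if report.verdict:
                    validated.append((q, sub))
        write_fasta(
            [
                SequenceRecord(id=f"window{k + 1}", sequence=sub.window_seq, description=sub.provenance)
                for k, (q, sub) in enumerate(validated)
            ],
            out / "validated_windows.fasta",
        )
        with open(out / "structures.txt", "w") as fh:
            fh.write(_header(cfg))
            for k, (q, sub) in enumerate(validated):
                s = hairpin.fold_structure(sub.window_seq, cfg.min_loop)
                fh.write(f">window{k + 1} {sub.provenance}\n{sub.window_seq}\n{s.dotbracket}\n")
        summary["stages"]["validated_windows"] = len(validated)

        # ------------------------------------------------------------------ dedupe
        stage = "dedupe"
        mature_records = [
            MatureMiRNA(
                id=f"window{k + 1}",
                sequence=sub.window_seq[
                    sub.mature_offset : sub.mature_offset + (sub.locus.end - sub.locus.start + 1)
                ],
            )
            for k, (q, sub) in enumerate(validated)
        ] or queries
        clusters = mature_clustering.dedupe_unique(mature_records, cfg.bracket_tolerance)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write(_header(cfg))
            fh.write("cluster\trepresentative\tsize\tmembers\n")
            for c in clusters.clusters:
                fh.write(f"{c.cluster_id}\t{c.representative}\t{c.size}\t{','.join(c.member_ids)}\n")
        summary["stages"]["unique_clusters"] = len(clusters)

        # ----------------------------------------------------------- identity/KS
        stage = "identity"
        stats: dict = {}
        if family is not None and len(family) >= 2:
            fam_aln = phylo.align_family(
                [SequenceRecord(id=m.id, sequence=m.sequence) for m in family]
            )
            fam_ident = mature_clustering.pairwise_identity_matrix(
                list(zip(fam_aln.taxa, fam_aln.rows))
            )
            stats["mature_fraction_at_90"] = fam_ident.fraction_at(0.90)
            if len(validated) >= 2:
                win_aln = phylo.align_family(
                    [
                        SequenceRecord(id=f"window{k + 1}", sequence=sub.window_seq)
                        for k, (q, sub) in enumerate(validated)
                    ]
                )
                win_ident = mature_clustering.pairwise_identity_matrix(
                    list(zip(win_aln.taxa, win_aln.rows))
                )
                stats["precursor_fraction_at_55"] = win_ident.fraction_at(0.55)
                d, p = mature_clustering.ks_two_sample(
                    fam_ident.pair_values, win_ident.pair_values
                )
                stats["ks_D"] = d
                stats["ks_p"] = p
            (out / "identity_stats.json").write_text(json.dumps(stats, indent=1))
        summary["stages"]["identity"] = stats

        # ------------------------------------------------------------------ targets
        stage = "targets"
        n_hits = 0
        with open(out / "targets.tsv", "w") as fh:
            fh.write(_header(cfg))
            fh.write("mirna\ttranscript\tstart\tend\tsite\tE\tUPE_proxy\tinhibition\n")
            reps = [
                MatureMiRNA(id=c.cluster_id, sequence=c.representative)
                for c in clusters.clusters
            ]
            for rep in reps:
                for t in transcripts:
                    for hit in target_scoring.scan_transcript(rep, t, cfg.scheme):
                        upe = target_scoring.upe_proxy(t.sequence, hit.start, hit.end)
                        fh.write(
                            f"{rep.id}\t{t.id}\t{hit.start}\t{hit.end}\t"
                            f"{hit.alignment.site_seq}\t{hit.alignment.E:g}\t{upe}\t"
                            f"{hit.inhibition}\n"
                        )
                        n_hits += 1
        summary["stages"]["target_hits"] = n_hits

        # ------------------------------------------------------------------ trees
        stage = "phylogeny"
        tree_input = None
        if family is not None and len(family) >= 3:
            tree_input = [SequenceRecord(id=m.id, sequence=m.sequence) for m in family]
        elif len(clusters.clusters) >= 3:
            tree_input = [
                SequenceRecord(id=c.cluster_id, sequence=c.representative)
                for c in clusters.clusters
            ]
        if tree_input is not None:
            aln = phylo.align_family(tree_input)
            tree = phylo.bootstrap_supports(aln, cfg.bootstrap, seed=cfg.seed)
            with open(out / "tree.nwk", "w") as fh:
                fh.write(tree.newick() + "\n")
            dm = phylo.p_distance_matrix(aln)
            with open(out / "distances.tsv", "w") as fh:
                fh.write(_header(cfg))
                fh.write("\t" + "\t".join(dm.taxa) + "\n")
                for i, t in enumerate(dm.taxa):
                    fh.write(t + "\t" + "\t".join(f"{dm.values[i, j]:.6f}" for j in range(len(dm.taxa))) + "\n")
            summary["stages"]["tree_taxa"] = len(tree_input)
        else:
            logger.warning("phylogeny skipped: fewer than 3 taxa")
            summary["stages"]["tree_taxa"] = 0
    except ConfigurationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline finished: %s", summary["stages"])
    return summary
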
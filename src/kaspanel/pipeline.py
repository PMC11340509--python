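"""End-to-end orchestration: simulate/load -> filter -> annotate -> stats ->
core collection -> KASP design -> core markers -> fingerprint.

A run is driven by one :class:`RunConfig` (loadable from YAML), uses a
single root seed from which every stochastic stage derives its own stream
(stable hash of the stage name, so adding stages never perturbs earlier
randomness), and emits a manifest JSON listing every artifact with its
SHA-256 checksum — two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    core_collection,
    io_formats,
    kasp_design,
    marker_panel,
    popgen_stats,
    synthetic_fixtures,
    variant_annotation,
    variant_filtering,
)

log = logging.getLogger("kaspanel")


@dataclass
class RunConfig:
    outdir: str = "kaspanel_run"
    seed: int = 17
    # exactly one of the two input modes
    simulate: dict | None = None          # SimulationConfig overrides
    inputs: dict | None = None            # {"vcf":..., "fasta":..., "gff":...}
    thresholds: dict = field(default_factory=dict)     # FilterThresholds
    design: dict = field(default_factory=dict)         # DesignConstraints
    screen: dict = field(default_factory=dict)         # CandidateScreenCriteria
    core_ratio: float = 0.3
    core_ratio_sweep: bool = False
    regulatory_window: int = 2000
    render_fingerprint: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must set exactly one of 'simulate' or 'inputs'"
            )
        if self.inputs is not None:
            for key in ("vcf", "fasta", "gff"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block lacks {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(self.inputs[key])


def stage_seed(root_seed: int, stage: str) -> int:
    """Stage-specific seed derived by stable hashing of the stage name."""
    return (root_seed + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    counts: dict[str, int] = {}

    def emit(name: str) -> Path:
        p = outdir / name
        files.append(p)
        return p

    # -- stage: inputs --------------------------------------------------
    if config.simulate is not None:
        sim_cfg = synthetic_fixtures.SimulationConfig(
            **{"seed": stage_seed(config.seed, "simulate"), **config.simulate}
        )
        genome, gene_models = synthetic_fixtures.simulate_reference(sim_cfg)
        io_formats.write_reference(genome, emit("genome.fasta"))
        io_formats.write_gene_models(gene_models, emit("genes.gff3"))
        truth = synthetic_fixtures.simulate_population(
            sim_cfg, genome, emit("variants.vcf")
        )
        truth.to_json(emit("truth.json"))
        vcf_path = outdir / "variants.vcf"
    else:
        genome = io_formats.read_reference(config.inputs["fasta"])
        gene_models = io_formats.read_gene_models(config.inputs["gff"])
        vcf_path = Path(config.inputs["vcf"])

    records, matrix = io_formats.read_variants(vcf_path)
    counts["input_variants"] = len(records)
    log.info("loaded %d variants x %d accessions", len(records),
             matrix.n_accessions)

    # -- stage: filter cascade ------------------------------------------
    t = variant_filtering.FilterThresholds(**config.thresholds)
    survivors, report = variant_filtering.run_cascade(records, matrix, genome, t)
    counts["cascade_survivors"] = len(survivors)
    for st in report.stages:
        counts[st["stage"]] = st["surviving_count"]
        log.info("%s: %d -> %d", st["stage"], st["input_count"],
                 st["surviving_count"])
    report.table().to_csv(emit("filter_report.tsv"), sep="\t", index=False)
    with open(emit("filter_report.json"), "w") as fh:
        json.dump({"stages": report.stages, "first_fail": report.first_fail},
                  fh, indent=1, sort_keys=True)
    surv_matrix = matrix.subset_loci([r.key for r in survivors])
    io_formats.write_variants(survivors, surv_matrix,
                              emit("survivors.vcf"), genome=genome)

    # -- stage: high-quality set for population genetics -----------------
    hq1, _ = variant_filtering.hard_filter(records, t)
    hq, _ = variant_filtering.quality_filter(hq1, matrix, t)
    hq_matrix = matrix.subset_loci([r.key for r in hq])
    counts["high_quality_snps"] = len(hq)

    # -- stage: annotation & spectrum ------------------------------------
    ann = variant_annotation.annotate_all(
        records, gene_models, genome, config.regulatory_window
    )
    ann.to_csv(emit("annotations.tsv"), sep="\t", index=False)
    spectrum = variant_annotation.substitution_spectrum(records, matrix)
    with open(emit("spectrum.json"), "w") as fh:
        json.dump(spectrum.to_dict(), fh, indent=1, sort_keys=True)

    # -- stage: per-locus stats, tree, PCA --------------------------------
    stats = popgen_stats.all_locus_stats(hq_matrix)
    popgen_stats.stats_table(stats).to_csv(
        emit("locus_stats.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    dm = popgen_stats.distance_matrix(hq_matrix)
    dm.dataframe().to_csv(emit("distances.tsv"), sep="\t", float_format="%.6g")
    io_formats.write_newick(popgen_stats.nj_tree(dm), emit("tree.nwk"))
    pc = popgen_stats.pca(hq_matrix, n_components=10)
    df = pc.dataframe()
    df.to_csv(emit("pca.tsv"), sep="\t", float_format="%.6g")
    with open(emit("pca_variance.json"), "w") as fh:
        json.dump(
            {"variance_fraction": [round(float(x), 6)
                                   for x in pc.variance_fraction[:10]]},
            fh, indent=1,
        )

    # -- stage: core collection -------------------------------------------
    core_seed = stage_seed(config.seed, "core_collection")
    if config.core_ratio_sweep:
        sweep = core_collection.ratio_sweep(hq_matrix, seed=core_seed)
        payload = [
            {"ratio": cs.ratio, "selected": cs.selected,
             "objective": cs.objective_value, **ev.to_dict()}
            for cs, ev in sweep
        ]
    else:
        cs = core_collection.select_core(hq_matrix, config.core_ratio,
                                         seed=core_seed, dist=dm)
        ev = core_collection.evaluate_core(hq_matrix, cs)
        payload = [{"ratio": cs.ratio, "selected": cs.selected,
                    "objective": cs.objective_value, **ev.to_dict()}]
    with open(emit("core_collection.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    counts["core_collection_size"] = len(payload[0]["selected"])

    # -- stage: KASP design ------------------------------------------------
    dc = kasp_design.DesignConstraints(**config.design)
    all_positions = [(r.contig_id, r.pos) for r in records]
    panel = kasp_design.design_panel(survivors, genome, all_positions, dc)
    kasp_design.panel_table(panel).to_csv(emit("kasp_panel.tsv"), sep="\t",
                                          index=False)
    counts["kasp_designed"] = sum(p.designed for p in panel)
    if panel:
        counts["kasp_conversion_rate_pct"] = round(
            kasp_design.conversion_rate(panel), 2
        )

    # -- stage: candidate screen + core markers + fingerprint ---------------
    sc = marker_panel.CandidateScreenCriteria(**config.screen)
    full_stats = {s.marker_id: s
                  for s in popgen_stats.all_locus_stats(surv_matrix)}
    region_of = dict(zip(ann["marker_id"], ann["region"]))
    designed_ids = {p.marker_id for p in panel if p.designed}
    positions = {r.marker_id: (r.contig_id, r.pos) for r in survivors}
    candidates = marker_panel.screen_candidates(
        full_stats, region_of, designed_ids, positions, sc
    )
    with open(emit("candidate_markers.txt"), "w") as fh:
        fh.write("\n".join(candidates) + "\n")
    counts["candidate_markers"] = len(candidates)
    if candidates:
        pic_of = {m: full_stats[m].pic for m in candidates}
        curve, core_markers, unresolvable = marker_panel.select_core_markers(
            matrix, candidates, pic_of
        )
        curve.table().to_csv(emit("saturation_curve.tsv"), sep="\t",
                             index=False, float_format="%.6g")
        with open(emit("core_markers.txt"), "w") as fh:
            fh.write("\n".join(core_markers) + "\n")
        counts["core_markers"] = len(core_markers)
        fp = marker_panel.build_fingerprint(matrix, core_markers)
        fp.codes.to_csv(emit("fingerprint.tsv"), sep="\t")
        with open(emit("fingerprint_report.json"), "w") as fh:
            json.dump(
                {
                    "identification_efficiency": marker_panel.
                    identification_efficiency(matrix, core_markers),
                    "identical_groups": fp.identical_groups,
                    "unresolvable_pairs": unresolvable,
                },
                fh, indent=1, sort_keys=True,
            )
        if config.render_fingerprint:
            marker_panel.render_fingerprint(fp, emit("fingerprint.png"))

    # -- manifest ------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "counts": counts,
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
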
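"""End-to-end orchestration: structure -> rearrangements -> partitions ->
alignment/filtering -> schemes -> trees -> marker ranking.

Every stage writes its artifact into the output directory before the next
stage runs, the configuration is echoed verbatim, and the whole run is
deterministic for a fixed seed.  Stage errors are raised with the stage and
offending genome/region named; per-region problems are logged and skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from plastomics.io import AnnotatedGenome, read_genbank, write_fasta
from plastomics import alignment as almod
from plastomics import phylo as phymod
from plastomics import rearrange as remod
from plastomics import regions as regmod
from plastomics import structure as stmod

logger = logging.getLogger("plastomics")

BEST_SCHEME = "coding+noncoding_edited"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat configuration with the study's thresholds as defaults."""

    output_dir: str
    input_dir: str | None = None  # directory of GenBank files, or None to simulate
    simulate_profile: str = "reduced"
    reference_id: str = "A_biternatum"
    outgroup_taxa: tuple[str, ...] = ("C_cujete", "T_tetragonolobum", "O_europaea")
    min_region_length: int = 50
    similarity_threshold: float = 0.65
    marker_min_len: int = 500
    marker_max_len: int = 1100
    ir_min_len: int = 1000
    block_max_nonconserved_run: int = 8
    block_min_block: int = 10
    outlier_k_sd: float = 2.0
    outlier_floor: float = 0.5
    bootstrap_reps: int = 100
    seed: int = 0
    external_aligner: str | None = None
    external_trees_dir: str | None = None
    run_ranking: bool = True

    def validate(self) -> None:
        if not self.reference_id:
            raise PipelineError("config error: reference_id is required")
        if not 0 < self.similarity_threshold < 1:
            raise PipelineError("similarity_threshold must be in (0, 1)")
        if self.min_region_length < 1 or self.marker_min_len > self.marker_max_len:
            raise PipelineError("invalid length thresholds")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "outgroup_taxa" in data:
            data["outgroup_taxa"] = tuple(data["outgroup_taxa"])
        return cls(**data)


@dataclass
class RunReport:
    structure_table: pd.DataFrame
    rearrangement_table: pd.DataFrame
    scheme_table: pd.DataFrame
    marker_table: pd.DataFrame | None
    tree_files: dict[str, str]
    warnings: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; returns the consolidated report.

    Requires at least four genomes (the outgroups plus one or more ingroup
    taxa).  Fails fast on structural errors; per-region alignment or tree
    problems are logged as warnings and the affected regions excluded.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_echo.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True, default=str)
    warnings_log: list[str] = []

    # ---- stage: load or simulate -----------------------------------------
    if config.input_dir:
        paths = sorted(Path(config.input_dir).glob("*.gb")) + sorted(
            Path(config.input_dir).glob("*.gbk")
        )
        genomes = [read_genbank(p) for p in paths]
    else:
        from plastomics.simulate import simulate_dataset, write_simulation

        sim = simulate_dataset(config.simulate_profile, seed=config.seed)
        write_simulation(sim, out / "simulated")
        genomes = sim.genomes
    if len(genomes) < 4:
        raise PipelineError(
            f"stage=load: need >= 4 genomes (3 outgroup + ingroup), got {len(genomes)}"
        )
    ids = [g.id for g in genomes]
    if config.reference_id not in ids:
        raise PipelineError(
            f"stage=load: reference {config.reference_id!r} not among genomes {ids}"
        )
    logger.info("stage=load n_genomes=%d", len(genomes))

    # ---- stage: structure -------------------------------------------------
    canon: dict[str, tuple[AnnotatedGenome, stmod.QuadripartiteLayout]] = {}
    for g in genomes:
        try:
            cg, layout = stmod.canonicalize(g, min_len=config.ir_min_len)
        except stmod.StructureNotFoundError as exc:
            raise PipelineError(f"stage=structure genome={g.id}: {exc}") from exc
        canon[g.id] = (cg, layout)
    structure_df = stmod.cross_species_structure_table(
        genomes, min_len=config.ir_min_len
    )
    _write_tsv(structure_df, out / "structure.tsv")
    logger.info("stage=structure rows=%d", len(structure_df))

    # ---- stage: rearrangement --------------------------------------------
    pairs = [canon[i] for i in sorted(canon)]
    rearr_df = remod.rearrangement_matrix(pairs, config.reference_id)
    _write_tsv(rearr_df, out / "rearrangement.tsv")
    ref_genome, ref_layout = canon[config.reference_id]
    ref_order = remod.gene_order(ref_genome, ref_layout)
    breakpoints: list[tuple[int, int]] = []
    for gid in sorted(canon):
        if gid == config.reference_id:
            continue
        g, lay = canon[gid]
        try:
            breakpoints.extend(
                remod.breakpoint_intervals(ref_order, remod.gene_order(g, lay))
            )
        except remod.InsufficientHomologyError as exc:
            warnings_log.append(f"rearrangement {gid}: {exc}")
    logger.info("stage=rearrangement breakpoint_intervals=%d", len(breakpoints))

    # ---- stage: partitioning ---------------------------------------------
    regions_by_genome = {
        gid: regmod.fragment_genome(
            canon[gid][0], canon[gid][1], config.min_region_length
        )
        for gid in sorted(canon)
    }
    for gid, regs in regions_by_genome.items():
        regmod.audit_disjoint(regs, canon[gid][0].length)
    groups, unassigned = regmod.group_by_similarity(
        regions_by_genome, config.reference_id, config.similarity_threshold
    )
    grouping_rows = [
        {
            "region": grp.region_name,
            "role": grp.role,
            "n_members": grp.n_members,
            "members": ";".join(sorted(grp.members)),
        }
        for grp in groups
    ]
    _write_tsv(pd.DataFrame(grouping_rows), out / "grouping.tsv")
    _write_tsv(
        pd.DataFrame(
            [{"genome": r.genome_id, "region": r.region_name} for r in unassigned]
        ),
        out / "unassigned_regions.tsv",
    )
    logger.info(
        "stage=partitioning groups=%d unassigned=%d", len(groups), len(unassigned)
    )

    # ---- stage: alignment / filtering ------------------------------------
    coding_alns: dict[str, almod.Alignment] = {}
    noncoding_edited: dict[str, almod.Alignment] = {}
    noncoding_filtered: dict[str, almod.Alignment] = {}
    group_index = {g.region_name: g for g in groups}
    for grp in groups:
        if grp.n_members < 2:
            warnings_log.append(f"align {grp.region_name}: single member, skipped")
            continue
        mode = "coding" if grp.role == "coding" else "noncoding"
        try:
            aln = almod.multiple_align(
                grp.sequences(), mode, grp.region_name,
                external_aligner=config.external_aligner,
            )
        except Exception as exc:  # pragma: no cover - external tools
            warnings_log.append(f"align {grp.region_name}: {exc}")
            continue
        if grp.role == "coding":
            _, filt = almod.block_filter(
                aln, config.block_max_nonconserved_run, config.block_min_block
            )
            if filt.length:
                coding_alns[grp.region_name] = filt
        else:
            edited, removed = almod.remove_outlier_rows(
                aln, config.outlier_k_sd, config.outlier_floor
            )
            if removed:
                warnings_log.append(
                    f"outliers {grp.region_name}: removed {','.join(removed)}"
                )
                edited = almod.multiple_align(
                    {gid: edited.ungapped(gid) for gid in edited.rows},
                    mode, grp.region_name,
                    external_aligner=config.external_aligner,
                )
            edited.provenance = "edited"
            if edited.length and edited.n_rows >= 2:
                noncoding_edited[grp.region_name] = edited
            _, filt = almod.block_filter(
                aln, config.block_max_nonconserved_run, config.block_min_block
            )
            if filt.length and filt.n_rows >= 3:
                filt, removed_f = almod.remove_outlier_rows(
                    filt, config.outlier_k_sd, config.outlier_floor
                )
                filt.provenance = "filtered"
            if filt.length and filt.n_rows >= 2:
                noncoding_filtered[grp.region_name] = filt
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for tag, table in (
        ("coding", coding_alns),
        ("noncoding_edited", noncoding_edited),
        ("noncoding_filtered", noncoding_filtered),
    ):
        for name, aln in table.items():
            safe = name.replace("/", "_")
            write_fasta(
                sorted(aln.rows.items()), aln_dir / f"{tag}.{safe}.fasta"
            )
    logger.info(
        "stage=alignment coding=%d nc_edited=%d nc_filtered=%d",
        len(coding_alns), len(noncoding_edited), len(noncoding_filtered),
    )

    # ---- stage: schemes ---------------------------------------------------
    schemes = regmod.build_schemes(coding_alns, noncoding_edited, noncoding_filtered)
    scheme_df = pd.DataFrame(
        [
            {
                "scheme": s.name,
                "alignment_length": s.alignment_length,
                "variable_sites": s.variable_sites,
                "pct_variation": s.percent_variation,
                "n_regions": len(s.region_names),
            }
            for s in schemes.values()
        ]
    )
    _write_tsv(scheme_df, out / "schemes.tsv")
    logger.info("stage=schemes n=%d", len(schemes))

    # ---- stage: trees -----------------------------------------------------
    taxa = sorted(canon)
    tree_files: dict[str, str] = {}
    scheme_trees: dict[str, object] = {}
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for name, scheme in schemes.items():
        rows = regmod.concatenate_scheme(scheme, taxa)
        try:
            tree = phymod.bootstrap_support(
                rows, n_reps=config.bootstrap_reps, seed=config.seed
            )
        except phymod.SaturationError as exc:
            raise PipelineError(f"stage=trees scheme={name}: {exc}") from exc
        scheme_trees[name] = tree
        path = tree_dir / f"{name.replace('+', '_plus_')}.nwk"
        tree.write(path=str(path), schema="newick", suppress_rooting=True,
                   unquoted_underscores=True)
        tree_files[name] = str(path)
    logger.info("stage=trees schemes=%d", len(scheme_trees))

    # ---- stage: marker ranking -------------------------------------------
    marker_df = None
    if config.run_ranking:
        reference_tree = phymod.root_and_prune(
            scheme_trees[BEST_SCHEME], list(config.outgroup_taxa)
        )
        ref_labels = {
            l.taxon.label for l in reference_tree.leaf_node_iter()
        }
        candidates, excluded = phymod.select_marker_candidates(
            groups, config.reference_id, breakpoints,
            ref_genome.length, config.marker_min_len, config.marker_max_len,
        )
        _write_tsv(
            pd.DataFrame(
                [{"region": k, "reason": v} for k, v in sorted(excluded.items())]
            ),
            out / "marker_exclusions.tsv",
        )
        per_alns: dict[str, almod.Alignment] = {}
        per_trees: dict[str, object] = {}
        for grp in candidates:
            aln = noncoding_edited.get(grp.region_name)
            if aln is None:
                warnings_log.append(f"rank {grp.region_name}: no edited alignment")
                continue
            # the ingroup must be complete; any surviving outgroup can root
            out_avail = sorted(set(config.outgroup_taxa) & set(aln.rows))
            if not ref_labels <= set(aln.rows) or not out_avail:
                warnings_log.append(f"rank {grp.region_name}: incomplete taxon set")
                continue
            needed = ref_labels | set(out_avail)
            try:
                t = phymod.nj_tree_from_alignment(
                    {gid: aln.rows[gid] for gid in sorted(needed)}
                )
                t = phymod.root_and_prune(t, out_avail)
            except (phymod.SaturationError, phymod.NonMonophyleticIngroupError,
                    ValueError) as exc:
                warnings_log.append(f"rank {grp.region_name}: {exc}")
                continue
            per_alns[grp.region_name] = aln
            per_trees[grp.region_name] = t
        if len(per_trees) >= 2:
            marker_df = phymod.rank_markers(
                per_alns, per_trees, reference_tree, groups=group_index
            )
            _write_tsv(marker_df, out / "markers.tsv")
        else:
            warnings_log.append("rank: fewer than two rankable regions")
        logger.info(
            "stage=ranking candidates=%d ranked=%d",
            len(candidates), 0 if marker_df is None else len(marker_df),
        )

    with open(out / "warnings.txt", "w") as fh:
        fh.write("\n".join(warnings_log) + ("\n" if warnings_log else ""))
    return RunReport(
        structure_table=structure_df,
        rearrangement_table=rearr_df,
        scheme_table=scheme_df,
        marker_table=marker_df,
        tree_files=tree_files,
        warnings=warnings_log,
    )
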
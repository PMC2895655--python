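"""Readers/writers for the standard formats and pipeline orchestration.

BED6 (0-based half-open) is the single interval dialect; GFF3
(1-based closed) is converted on read. Matrices travel as TSV with a
header row and a row-key column. The full pipeline chains enrichment
calling per antibody and timepoint, the dual-antibody intersection,
region merging, co-occupancy, differential expression per mutant and
timepoint, target integration and reporter-mode classification, and
emits a consistency-checked run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip as chipmod
from . import expression as exprmod
from . import integration as intmod
from . import reporters as repmod
from .chip import BoundRegion, ChipReplicateMatrix, TilingFragment
from .config import PipelineConfig
from .integration import GeneModel

__all__ = [
    "read_regions_bed",
    "write_regions_bed",
    "write_fragments_bed",
    "write_sites_bed",
    "read_fragments_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_genes_gff3",
    "write_genes_gff3",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_expression_tensor",
    "RunReport",
    "run_pipeline",
    "make_report",
]

logger = logging.getLogger("coregmap")


# ----------------------------------------------------------------------
# BED
def read_regions_bed(path: str | Path) -> list[BoundRegion]:
    """Read a BED6 file into BoundRegions (0-based half-open).

    Track and comment lines are skipped; strand is accepted and
    ignored. Malformed coordinates raise a parse error naming the line.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = parts[3] if len(parts) > 3 else f"region{lineno}"
            score = parts[4] if len(parts) > 4 else "0"
            min_fdr = float("nan")
            try:
                s = float(score)
                if s > 0:
                    min_fdr = 10 ** (-s / 10.0)
            except ValueError:
                pass
            regions.append(
                BoundRegion(chrom, start, end, fragment_ids=[name], min_fdr=min_fdr)
            )
    return regions


def _fdr_score(min_fdr: float) -> int:
    """BED score = -10*log10(min FDR), capped at 1000."""
    if not np.isfinite(min_fdr) or min_fdr <= 0:
        return 1000
    return int(min(round(-10.0 * np.log10(min_fdr)), 1000))


def write_regions_bed(regions: list[BoundRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, reg in enumerate(regions):
            name = f"region{i + 1}"
            tps = ",".join(sorted(reg.timepoints)) if reg.timepoints else "."
            fh.write(
                f"{reg.chrom}\t{reg.start}\t{reg.end}\t{name}"
                f"\t{_fdr_score(reg.min_fdr)}\t+\t{tps}\n"
            )


def write_fragments_bed(fragments: list[TilingFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t+\n")


def read_fragments_bed(path: str | Path) -> list[TilingFragment]:
    fragments = []
    for reg in read_regions_bed(path):
        fragments.append(
            TilingFragment(
                id=reg.fragment_ids[0], chrom=reg.chrom, start=reg.start, end=reg.end
            )
        )
    return fragments


def write_sites_bed(sites, path: str | Path) -> None:
    """Write planted truth sites as BED6 (name = host gene)."""
    with open(path, "w") as fh:
        for s in sites:
            tps = ",".join(s.timepoints)
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.host_gene or '.'}\t0\t+\t{tps}\n"
            )


# ----------------------------------------------------------------------
# TSV matrices
def read_matrix_tsv(
    path: str | Path, expected_columns: list[str] | None = None
) -> pd.DataFrame:
    """Row-keyed numeric TSV with a header; validates keys and cells."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row keys {dupes[:5]}")
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing expected columns {missing}")
    non_numeric = [
        c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])
    ]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric cells in columns {non_numeric}")
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        raise ValueError(f"{path}: {n} missing cells")
    return df


def write_matrix_tsv(
    df: pd.DataFrame, path: str | Path, index_name: str = "id"
) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.6g")


# ----------------------------------------------------------------------
# GFF3 genes (1-based closed on disk, half-open in memory)
def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id};muscle_expressed={int(g.muscle_expressed)}"
            fh.write(
                f"{g.chrom}\tcoregmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in fields:
                raise ValueError(f"{path}:{lineno}: gene without ID attribute")
            genes.append(
                GeneModel(
                    id=fields["ID"],
                    chrom=chrom,
                    strand=strand,
                    start=int(start) - 1,  # to 0-based half-open
                    end=int(end),
                    muscle_expressed=bool(int(fields.get("muscle_expressed", "0"))),
                )
            )
    return genes


def write_annotation_tsv(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmuscle_expressed\n")
        for g in genes:
            fh.write(f"{g.id}\t{int(g.muscle_expressed)}\n")


def read_annotation_tsv(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t")
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return dict(zip(df["gene"], df["muscle_expressed"].astype(bool)))


def read_expression_tensor(path: str | Path, mutant: str) -> tuple[np.ndarray, list[str]]:
    """Read a ``<mutant>_t<k>_rep<j>`` TSV back into (genes, tp, rep)."""
    df = read_matrix_tsv(path)
    tps, reps = set(), set()
    for col in df.columns:
        prefix = f"{mutant}_t"
        if not col.startswith(prefix):
            raise ValueError(f"{path}: unexpected column {col!r} for {mutant}")
        t, r = col[len(prefix):].split("_rep")
        tps.add(int(t))
        reps.add(int(r))
    n_tp, n_rep = max(tps), max(reps)
    tensor = np.empty((len(df), n_tp, n_rep))
    for t in range(1, n_tp + 1):
        for r in range(1, n_rep + 1):
            tensor[:, t - 1, r - 1] = df[f"{mutant}_t{t}_rep{r}"].to_numpy()
    return tensor, list(df.index)


# ----------------------------------------------------------------------
# Orchestration
@dataclass
class RunReport:
    """Summary of a full pipeline run with internal consistency checks."""

    n_fragments: int = 0
    bound_counts: dict[str, int] = field(default_factory=dict)
    venn: dict[str, int] = field(default_factory=dict)
    pct_A_cobound: float = float("nan")
    n_targets: dict[str, int] = field(default_factory=dict)
    target_overlap: int = 0
    target_overlap_pct: float = float("nan")
    fisher_p: float = float("nan")
    n_downstream: dict[str, int] = field(default_factory=dict)
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    mode_tally: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.venn:
            if self.venn["cobound"] > min(
                self.bound_counts.get("A", 0), self.bound_counts.get("B", 0)
            ):
                raise ValueError("co-bound count exceeds a bound count")
        if self.n_targets and self.target_overlap > min(self.n_targets.values()):
            raise ValueError("target overlap exceeds a target-set size")

    def to_dict(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "bound_counts": self.bound_counts,
            "venn": self.venn,
            "pct_A_cobound": self.pct_A_cobound,
            "n_targets": self.n_targets,
            "target_overlap": self.target_overlap,
            "target_overlap_pct": self.target_overlap_pct,
            "fisher_p": self.fisher_p,
            "n_downstream": self.n_downstream,
            "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
            "mode_tally": self.mode_tally,
            "config": self.config,
            "version": self.version,
            # stage timings stay out of the rendered report so identical
            # config+seed runs produce byte-identical files
        }


def call_bound_regions(
    matrix: ChipReplicateMatrix,
    fragments: list[TilingFragment],
    fdr_max: float = 0.02,
    min_fold: float = 1.5,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[BoundRegion]:
    """Enrichment calling for one factor: rank products per antibody and
    timepoint, permutation FDR, thresholding, dual-antibody
    intersection, and merging across timepoints."""
    frag_by_id = {f.id: f for f in fragments}
    bound_by_tp: dict[str, set[str]] = {}
    fdr_by_tp: dict[str, pd.Series] = {}
    ss = np.random.SeedSequence(seed)
    antibodies = matrix.antibodies()
    timepoints = matrix.timepoints()
    children = iter(ss.spawn(len(antibodies) * len(timepoints)))
    for tp in timepoints:
        per_ab = []
        fdr_min = None
        for ab in antibodies:
            rp = chipmod.compute_rank_products(matrix, ab, tp)
            rp = chipmod.permutation_fdr(
                rp, n_perm=n_perm, seed=next(children), exhaustive=False
            )
            calls = chipmod.call_enriched(rp, fdr_max=fdr_max, min_fold=min_fold)
            per_ab.append(calls)
            fdr_min = calls["fdr"] if fdr_min is None else np.minimum(fdr_min, calls["fdr"])
        bound = per_ab[0]
        for other in per_ab[1:]:
            bound_ids = chipmod.intersect_antibodies(bound, other)
            keep = bound.index.isin(bound_ids)
            bound = bound.copy()
            bound["significant"] = bound["significant"] & keep
        bound_by_tp[tp] = set(bound.index[bound["significant"]])
        fdr_by_tp[tp] = pd.Series(fdr_min.to_numpy(), index=per_ab[0].index)
    return chipmod.merge_bound_regions(bound_by_tp, frag_by_id, fdr_by_tp)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis on a fixture bundle directory.

    Stages: ChIP enrichment calling per factor -> dual-antibody
    intersection -> region merging -> co-occupancy -> differential
    expression per mutant -> direct-target integration with overlap
    significance and response-profile clustering -> reporter mode
    classification. All intermediates are written under the output
    directory; the same config and seed give an identical report.
    """
    from importlib.metadata import version as pkg_version

    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    try:
        report.version = pkg_version("coregmap")
    except Exception:
        report.version = "unknown"

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # --- ChIP enrichment per factor
    t0 = _stage("chip-call")
    fragments = read_fragments_bed(fixture / "fragments.bed")
    report.n_fragments = len(fragments)
    regions: dict[str, list[BoundRegion]] = {}
    for i, factor in enumerate(("A", "B")):
        path = fixture / f"chip_{factor}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stage chip-call: missing matrix {path}")
        matrix = ChipReplicateMatrix(read_matrix_tsv(path))
        regions[factor] = call_bound_regions(
            matrix,
            fragments,
            fdr_max=config.fdr_max,
            min_fold=config.min_fold,
            n_perm=config.n_perm,
            seed=config.seed + i,
        )
        write_regions_bed(regions[factor], out / f"bound_regions_{factor}.bed")
        report.bound_counts[factor] = len(regions[factor])
    report.stage_seconds["chip_call"] = time.perf_counter() - t0

    # --- co-occupancy
    t0 = _stage("co-occupancy")
    n_A, n_B, n_cob, pct = chipmod.co_occupancy(regions["A"], regions["B"])
    _, _, n_cob_B, _ = chipmod.co_occupancy(regions["B"], regions["A"])
    report.venn = {"A_only": n_A - n_cob, "B_only": n_B - n_cob_B, "cobound": n_cob}
    report.pct_A_cobound = pct
    report.stage_seconds["co_occupancy"] = time.perf_counter() - t0

    # --- differential expression
    t0 = _stage("de-call")
    tensors = {}
    gene_ids: list[str] = []
    for mutant in ("A_mut", "B_mut"):
        path = fixture / f"expression_{mutant}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stage de-call: missing matrix {path}")
        tensors[mutant], gene_ids = read_expression_tensor(path, mutant)
    de = exprmod.analyze_timecourse(
        tensors,
        gene_ids,
        q_max=config.q_max,
        log2fc_min=config.log2fc_min,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)
    gene_calls = exprmod.gene_level_calls(de)
    gene_calls.to_csv(out / "de_gene_calls.tsv", sep="\t", index=False)
    downstream = {
        m: set(
            gene_calls[(gene_calls["mutant"] == m) & gene_calls["downstream"]]["gene"]
        )
        for m in ("A_mut", "B_mut")
    }
    report.n_downstream = {m: len(v) for m, v in downstream.items()}
    report.stage_seconds["de_call"] = time.perf_counter() - t0

    # --- integration
    t0 = _stage("integrate")
    genes = read_genes_gff3(fixture / "genes.gff3")
    annot = read_annotation_tsv(fixture / "annotations.tsv")
    genes = [
        GeneModel(
            id=g.id, chrom=g.chrom, strand=g.strand, start=g.start, end=g.end,
            muscle_expressed=annot.get(g.id, g.muscle_expressed),
        )
        for g in genes
    ]
    targets: dict[str, set[str]] = {}
    for factor, mutant in (("A", "A_mut"), ("B", "B_mut")):
        assignments = intmod.assign_regions_to_genes(
            regions[factor], genes, de_genes=downstream[mutant],
            window_bp=config.window_bp,
        )
        tbl = intmod.define_direct_targets(assignments, downstream[mutant], genes)
        tbl.to_csv(out / f"direct_targets_{factor}.tsv", sep="\t", index=False)
        targets[factor] = set(tbl["gene"])
        report.n_targets[factor] = len(targets[factor])
    if targets["A"]:
        overlap, pct_t, fisher_p = intmod.overlap_significance(
            targets["A"], targets["B"], universe_size=len(genes)
        )
        report.target_overlap = overlap
        report.target_overlap_pct = pct_t
        report.fisher_p = fisher_p
    union_targets = sorted(targets["A"] | targets["B"])
    if len(union_targets) >= config.k:
        profiles = intmod.build_response_profiles(de, gene_subset=union_targets)
        labels, _ = intmod.cluster_response_profiles(
            profiles, k=config.k, seed=config.seed
        )
        labels.to_csv(out / "cluster_labels.tsv", sep="\t")
        report.cluster_sizes = labels.value_counts().sort_index().to_dict()
    report.stage_seconds["integrate"] = time.perf_counter() - t0

    # --- reporter modes
    t0 = _stage("classify-modes")
    rep_path = fixture / "reporters.tsv"
    if config.modes_stage and not rep_path.exists():
        raise FileNotFoundError(
            f"stage classify-modes: missing reporter table {rep_path}"
        )
    if config.modes_stage:
        table = pd.read_csv(rep_path, sep="\t")
        calls = []
        for enh, g in table.groupby("enhancer", sort=True):
            calls.append(repmod.classify_mode(g, alpha=config.alpha))
        mode_df = pd.DataFrame(
            {
                "enhancer": [c.enhancer for c in calls],
                "mode": [c.mode for c in calls],
                "p_value": [c.p_value for c in calls],
                "stars": [c.stars for c in calls],
                "dose_dependence": [c.dose_dependence for c in calls],
                "f_A": [c.f_A for c in calls],
                "f_B": [c.f_B for c in calls],
                "f_AB": [c.f_AB for c in calls],
                "expected_additive": [c.expected_additive for c in calls],
            }
        )
        mode_df.to_csv(out / "mode_calls.tsv", sep="\t", index=False)
        report.mode_tally = mode_df["mode"].value_counts().to_dict()
    report.stage_seconds["classify_modes"] = time.perf_counter() - t0

    report.validate()
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    return report


def make_report(intermediates: dict) -> RunReport:
    """Assemble a RunReport from precomputed pipeline intermediates.

    ``intermediates`` may contain ``regions`` ({factor: BoundRegion
    list}), ``targets`` ({factor: set of gene ids}) with
    ``universe_size``, ``cluster_labels`` (Series) and ``mode_calls``
    (list of ModeCall). Consistency is validated before returning.
    """
    report = RunReport()
    regions = intermediates.get("regions")
    if regions:
        n_A, n_B, n_cob, pct = chipmod.co_occupancy(regions["A"], regions["B"])
        _, _, n_cob_B, _ = chipmod.co_occupancy(regions["B"], regions["A"])
        report.bound_counts = {"A": n_A, "B": n_B}
        report.venn = {"A_only": n_A - n_cob, "B_only": n_B - n_cob_B, "cobound": n_cob}
        report.pct_A_cobound = pct
    targets = intermediates.get("targets")
    if targets is not None:
        report.n_targets = {f: len(t) for f, t in targets.items()}
        if targets.get("A"):
            overlap, pct_t, p = intmod.overlap_significance(
                targets["A"], targets["B"], intermediates["universe_size"]
            )
            report.target_overlap = overlap
            report.target_overlap_pct = pct_t
            report.fisher_p = p
    labels = intermediates.get("cluster_labels")
    if labels is not None:
        report.cluster_sizes = pd.Series(labels).value_counts().sort_index().to_dict()
    calls = intermediates.get("mode_calls")
    if calls is not None:
        report.mode_tally = pd.Series([c.mode for c in calls]).value_counts().to_dict()
    report.validate()
    return report
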
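"""Synthetic microarray study with planted ground truth.

Generates the three data types the analysis consumes, with known truth
so every stage can be benchmarked by parameter recovery:

* a ChIP tiling-array experiment per factor — overlapping 3 kb tiles,
  two antibodies with four replicate IPs plus four matched mock
  precipitations at each of two timepoints, hybridised against a
  genomic reference. Planted bound sites contribute log2 enrichment
  proportional to their fractional overlap with each tile, scaled by a
  per-antibody efficiency; mocks are pure noise. Each antibody also
  carries an independent off-target site set, which the dual-antibody
  rule is meant to remove.
* a mutant-vs-wild-type expression timecourse — six one-hour
  timepoints, four replicate direct hybridisations per mutant, with
  per-gene response classes (down in both mutants, up in the A mutant,
  divergent, down in A only, null) mirroring the cluster structure of
  dual-mutant profiling.
* dual-titration luciferase reporter tables — factor doses 1/10 ng
  alone and combined, with enhancers planted as additive, cooperative
  or repressive and multiplicative lognormal replicate noise.

Genes sit on a regular grid; each planted site is placed inside the
locus of a "host" gene drawn from the response classes that match the
factor, so binding, expression response and annotation are coherently
linked in the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import ChipReplicateMatrix, TilingFragment
from .config import SimulationConfig
from .integration import GeneModel

__all__ = [
    "GroundTruth",
    "PlantedSite",
    "simulate_chip_experiment",
    "simulate_expression_timecourse",
    "simulate_reporter_assays",
    "simulate_all",
    "write_fixture_bundle",
    "TIMEPOINTS",
    "MUTANTS",
]

TIMEPOINTS = ("T1", "T2")  # 6-8 h and 8-10 h collection windows
MUTANTS = ("A_mut", "B_mut")

#: response classes whose genes change in the A mutant
A_RESPONSIVE = {"down_both", "up_in_A_mut", "divergent", "down_A_only"}
#: response classes whose genes change in the B mutant
B_RESPONSIVE = {"down_both", "divergent"}


@dataclass(frozen=True)
class PlantedSite:
    """A planted bound site with its host gene and activity windows."""

    chrom: str
    start: int
    end: int
    host_gene: str
    timepoints: tuple[str, ...]
    factors: tuple[str, ...]  # subset of ("A", "B")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every fixture bundle."""

    sites: list[PlantedSite] = field(default_factory=list)
    gene_class: dict[str, str] = field(default_factory=dict)
    gene_region_links: dict[str, list[int]] = field(default_factory=dict)
    enhancer_mode: dict[str, str] = field(default_factory=dict)
    enhancer_params: dict[str, dict] = field(default_factory=dict)

    def sites_for(self, factor: str, timepoint: str | None = None) -> list[PlantedSite]:
        out = [s for s in self.sites if factor in s.factors]
        if timepoint is not None:
            out = [s for s in out if timepoint in s.timepoints]
        return out

    def target_genes(self, factor: str, genes: list[GeneModel]) -> set[str]:
        """Planted direct targets: hosting a site for the factor, responsive
        in the matching mutant, and tissue-annotated."""
        responsive = A_RESPONSIVE if factor == "A" else B_RESPONSIVE
        annotated = {g.id for g in genes if g.muscle_expressed}
        return {
            s.host_gene
            for s in self.sites_for(factor)
            if self.gene_class.get(s.host_gene) in responsive
            and s.host_gene in annotated
        }

    def to_dict(self) -> dict:
        return {
            "sites": [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "host_gene": s.host_gene,
                    "timepoints": list(s.timepoints),
                    "factors": list(s.factors),
                }
                for s in self.sites
            ],
            "gene_class": self.gene_class,
            "gene_region_links": self.gene_region_links,
            "enhancer_mode": self.enhancer_mode,
            "enhancer_params": self.enhancer_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        truth = cls()
        truth.sites = [
            PlantedSite(
                chrom=s["chrom"],
                start=int(s["start"]),
                end=int(s["end"]),
                host_gene=s["host_gene"],
                timepoints=tuple(s["timepoints"]),
                factors=tuple(s["factors"]),
            )
            for s in d["sites"]
        ]
        truth.gene_class = dict(d["gene_class"])
        truth.gene_region_links = {k: list(v) for k, v in d["gene_region_links"].items()}
        truth.enhancer_mode = dict(d["enhancer_mode"])
        truth.enhancer_params = dict(d["enhancer_params"])
        return truth


CHROM = "chrS"


def make_tile_grid(config: SimulationConfig) -> list[TilingFragment]:
    """Overlapping tile grid: floor((L - tile)/step) + 1 fragments."""
    n_tiles = (config.genome_length - config.tile_length) // config.tile_step + 1
    if n_tiles < 1:
        raise ValueError("tile grid does not cover the genome")
    width = len(str(n_tiles))
    return [
        TilingFragment(
            id=f"frag{i + 1:0{width}d}",
            chrom=CHROM,
            start=i * config.tile_step,
            end=i * config.tile_step + config.tile_length,
        )
        for i in range(n_tiles)
    ]


def _gene_grid(config: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Genes on a regular grid of slots; span is the central 60% of a slot."""
    spacing = config.genome_length // config.n_genes
    if spacing <= config.site_length:
        raise ValueError(
            "gene slots are smaller than planted sites; reduce n_genes "
            "or site_length"
        )
    width = len(str(config.n_genes))
    genes = []
    for i in range(config.n_genes):
        slot = i * spacing
        start = slot + int(spacing * 0.2)
        end = slot + int(spacing * 0.8)
        genes.append(
            {
                "id": f"g{i + 1:0{width}d}",
                "slot": i,
                "chrom": CHROM,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "muscle_expressed": bool(rng.random() < 0.6),
            }
        )
    return genes


def _plant_layout(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[dict], GroundTruth]:
    """Draw gene classes, choose host genes and place planted sites."""
    genes = _gene_grid(config, rng)
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    drawn = rng.choice(len(classes), size=config.n_genes, p=probs)
    truth = GroundTruth()
    for g, ci in zip(genes, drawn):
        truth.gene_class[g["id"]] = classes[ci]

    n_cob = int(round(config.cobind_fraction * config.n_bound_A))
    n_cob = min(n_cob, config.n_bound_A, config.n_bound_B)
    n_a_only = config.n_bound_A - n_cob
    n_b_only = config.n_bound_B - n_cob

    by_class: dict[str, list[dict]] = {}
    for g in genes:
        by_class.setdefault(truth.gene_class[g["id"]], []).append(g)

    def _draw_hosts(pool_classes: set[str], n: int, used: set[str]) -> list[dict]:
        pool = [
            g for c in sorted(pool_classes) for g in by_class.get(c, [])
            if g["id"] not in used
        ]
        if len(pool) < n:
            raise ValueError(
                f"not enough genes of classes {sorted(pool_classes)} to host "
                f"{n} planted sites; adjust class_proportions or n_genes"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]

    used: set[str] = set()
    hosts_cob = _draw_hosts(A_RESPONSIVE & B_RESPONSIVE, n_cob, used)
    used |= {g["id"] for g in hosts_cob}
    hosts_a = _draw_hosts(A_RESPONSIVE - B_RESPONSIVE, n_a_only, used)
    used |= {g["id"] for g in hosts_a}
    hosts_b = _draw_hosts(B_RESPONSIVE, n_b_only, used)
    used |= {g["id"] for g in hosts_b}

    spacing = config.genome_length // config.n_genes

    def _site_for(host: dict, factors: tuple[str, ...]) -> PlantedSite:
        # centred in the host gene's slot so sites never collide
        slot = host["slot"] * spacing
        start = slot + (spacing - config.site_length) // 2
        # hosts of planted sites always carry the tissue annotation
        host["muscle_expressed"] = True
        tp_draw = rng.random()
        if tp_draw < 0.4:
            tps: tuple[str, ...] = TIMEPOINTS
        elif tp_draw < 0.7:
            tps = (TIMEPOINTS[0],)
        else:
            tps = (TIMEPOINTS[1],)
        return PlantedSite(
            chrom=CHROM,
            start=start,
            end=start + config.site_length,
            host_gene=host["id"],
            timepoints=tps,
            factors=factors,
        )

    for host in hosts_cob:
        truth.sites.append(_site_for(host, ("A", "B")))
    for host in hosts_a:
        truth.sites.append(_site_for(host, ("A",)))
    for host in hosts_b:
        truth.sites.append(_site_for(host, ("B",)))
    truth.sites.sort(key=lambda s: s.start)

    # truth bookkeeping: every responsive gene links to >= 1 planted region
    a_idx = [i for i, s in enumerate(truth.sites) if "A" in s.factors]
    b_idx = [i for i, s in enumerate(truth.sites) if "B" in s.factors]
    host_of = {s.host_gene: i for i, s in enumerate(truth.sites)}
    j_a = j_b = 0
    for g in genes:
        cls = truth.gene_class[g["id"]]
        if cls == "null":
            continue
        if g["id"] in host_of:
            truth.gene_region_links[g["id"]] = [host_of[g["id"]]]
        elif cls in B_RESPONSIVE and b_idx:
            truth.gene_region_links[g["id"]] = [b_idx[j_b % len(b_idx)]]
            j_b += 1
        elif a_idx:
            truth.gene_region_links[g["id"]] = [a_idx[j_a % len(a_idx)]]
            j_a += 1
    return genes, truth


def build_layout(config: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Deterministic genome layout (genes, planted sites) for a config."""
    genes_raw, truth = _plant_layout(config, config.rng_layout())
    genes = [
        GeneModel(
            id=g["id"],
            chrom=g["chrom"],
            strand=g["strand"],
            start=g["start"],
            end=g["end"],
            muscle_expressed=g["muscle_expressed"],
        )
        for g in genes_raw
    ]
    return genes, truth


def _fractional_overlap(site: PlantedSite, frag: TilingFragment) -> float:
    ov = min(site.end, frag.end) - max(site.start, frag.start)
    return max(ov, 0) / (site.end - site.start)


def simulate_chip_experiment(
    config: SimulationConfig,
    layout: tuple[list[GeneModel], GroundTruth] | None = None,
) -> tuple[dict[str, ChipReplicateMatrix], list[TilingFragment], GroundTruth]:
    """Simulate the tiling-array ChIP experiment for both factors.

    Returns one :class:`ChipReplicateMatrix` per factor (columns cover
    both antibodies, IP and mock conditions, both timepoints), the tile
    grid, and the planted truth. A tile's IP log2 ratio is the sum over
    planted sites of effect x fractional site overlap x antibody
    efficiency, plus Gaussian noise; mock columns are pure noise.
    """
    genes, truth = layout if layout is not None else build_layout(config)
    fragments = make_tile_grid(config)
    rng = config.rng_chip()
    starts = np.array([f.start for f in fragments])
    n_frag = len(fragments)

    matrices: dict[str, ChipReplicateMatrix] = {}
    for factor in ("A", "B"):
        # per-antibody off-target sites, independent of the shared truth
        offtargets: list[list[PlantedSite]] = []
        for _ in range(config.n_antibodies):
            sites = []
            for _ in range(config.n_offtarget_per_antibody):
                s = int(rng.integers(0, config.genome_length - config.site_length))
                tp = TIMEPOINTS[int(rng.integers(0, len(TIMEPOINTS)))]
                sites.append(
                    PlantedSite(CHROM, s, s + config.site_length, "", (tp,), ())
                )
            offtargets.append(sites)

        true_sites = truth.sites_for(factor)
        columns: dict[str, np.ndarray] = {}
        for tp in TIMEPOINTS:
            signal_true = np.zeros(n_frag)
            for site in true_sites:
                if tp not in site.timepoints:
                    continue
                lo = np.searchsorted(starts, site.start - config.tile_length, side="left")
                hi = np.searchsorted(starts, site.end, side="left")
                for i in range(lo, hi):
                    signal_true[i] += config.chip_effect_log2 * _fractional_overlap(
                        site, fragments[i]
                    )
            for ab in range(config.n_antibodies):
                eff = config.antibody_efficiency[ab]
                signal = signal_true * eff
                off = np.zeros(n_frag)
                for site in offtargets[ab]:
                    if tp not in site.timepoints:
                        continue
                    lo = np.searchsorted(
                        starts, site.start - config.tile_length, side="left"
                    )
                    hi = np.searchsorted(starts, site.end, side="left")
                    for i in range(lo, hi):
                        off[i] += config.chip_effect_log2 * eff * _fractional_overlap(
                            site, fragments[i]
                        )
                for rep in range(config.n_ip_replicates_per_antibody):
                    noise = rng.normal(0.0, config.chip_noise_sd, n_frag)
                    columns[f"ab{ab + 1}_ip_{tp}_r{rep + 1}"] = signal + off + noise
                for rep in range(config.n_mock):
                    columns[f"ab{ab + 1}_mock_{tp}_r{rep + 1}"] = rng.normal(
                        0.0, config.chip_noise_sd, n_frag
                    )
        data = pd.DataFrame(columns, index=pd.Index([f.id for f in fragments], name="fragment"))
        matrices[factor] = ChipReplicateMatrix(data)
    return matrices, fragments, truth


#: per-class mean log2(mutant/wt) trajectory templates; entries give
#: (mutant, affected timepoint indices, sign)
_CLASS_EFFECTS: dict[str, list[tuple[str, tuple[int, ...], float]]] = {
    "down_both": [("A_mut", (2, 3, 4, 5), -1.0), ("B_mut", (2, 3, 4, 5), -1.0)],
    "up_in_A_mut": [("A_mut", (2, 3, 4, 5), +1.0)],
    "divergent": [("A_mut", (3, 4, 5), -1.0), ("B_mut", (3, 4, 5), +1.0)],
    "down_A_only": [("A_mut", (2, 3, 4, 5), -1.0)],
    "null": [],
}


def class_mean_trajectories(
    cls: str, n_timepoints: int, effect: float
) -> dict[str, np.ndarray]:
    """Planted mean log2(mutant/wt) trajectory of a response class."""
    out = {m: np.zeros(n_timepoints) for m in MUTANTS}
    for mutant, tps, sign in _CLASS_EFFECTS[cls]:
        for t in tps:
            if t < n_timepoints:
                out[mutant][t] = sign * effect
    return out


def simulate_expression_timecourse(
    config: SimulationConfig,
    layout: tuple[list[GeneModel], GroundTruth] | None = None,
) -> tuple[dict[str, np.ndarray], list[str], GroundTruth]:
    """Simulate the mutant expression timecourses for both mutants.

    Returns ``{mutant: array (genes, timepoints, replicates)}`` of
    normalised log2(mutant/wt) ratios, the gene id list, and the truth.
    """
    genes, truth = layout if layout is not None else build_layout(config)
    rng = config.rng_expression()
    gene_ids = [g.id for g in genes]
    shape = (len(genes), config.n_timepoints_expr, config.n_expr_replicates)
    tensors = {}
    means = {m: np.zeros(shape[:2]) for m in MUTANTS}
    for i, gid in enumerate(gene_ids):
        traj = class_mean_trajectories(
            truth.gene_class[gid], config.n_timepoints_expr, config.expr_effect_log2
        )
        for m in MUTANTS:
            means[m][i] = traj[m]
    for m in MUTANTS:
        noise = rng.normal(0.0, config.expr_noise_sd, shape)
        tensors[m] = means[m][:, :, None] + noise
    return tensors, gene_ids, truth


_REPORTER_DOSES = (0.0, 1.0, 10.0)


def _dose_response(f_max: float, dose: float) -> float:
    """Single-factor fold at a dose: full effect at 10 ng, half at 1 ng."""
    if dose <= 0:
        return 1.0
    if dose >= 10.0:
        return f_max
    return 1.0 + 0.5 * (f_max - 1.0)


def reporter_condition_mean(
    mode: str,
    f_A_max: float,
    f_B_max: float,
    dose_A: float,
    dose_B: float,
    synergy_gamma: float,
    repression_kappa: float,
) -> float:
    """Generative mean fold change of one condition under a planted mode."""
    if dose_A < 0 or dose_B < 0:
        raise ValueError("doses must be non-negative")
    f_a = _dose_response(f_A_max, dose_A)
    f_b = _dose_response(f_B_max, dose_B)
    if mode == "repressive":
        # factor A alone sits at baseline and quenches B's activation
        if dose_B == 0:
            return 1.0
        return 1.0 + (f_b - 1.0) * float(np.exp(-repression_kappa * dose_A))
    if dose_A == 0 and dose_B == 0:
        return 1.0
    base = f_a + f_b - 1.0
    if mode == "additive":
        return base
    if mode == "cooperative":
        if dose_A > 0 and dose_B > 0:
            return base * (1.0 + synergy_gamma)
        return base
    raise ValueError(f"unknown reporter mode {mode!r}")


def simulate_reporter_assays(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate dual-titration luciferase tables for all enhancers.

    Conditions span factor doses {0, 1, 10} ng alone and in all
    combinations, with the reporter-only (0, 0) control. Replicate
    activities carry multiplicative lognormal noise with coefficient of
    variation ``reporter_cv``. Returns the long replicate table and a
    truth object holding each enhancer's planted mode.
    """
    rng = config.rng_reporter()
    truth = GroundTruth()
    modes = list(config.reporter_modes)
    probs = np.array([config.reporter_modes[m] for m in modes])
    sigma = float(np.sqrt(np.log1p(config.reporter_cv**2)))
    sigma_renilla = sigma / 2.0
    rows = []
    width = len(str(config.n_enhancers))
    for e in range(config.n_enhancers):
        name = f"enh{e + 1:0{width}d}"
        mode = modes[int(rng.choice(len(modes), p=probs))]
        if mode == "cooperative":
            f_A_max = float(rng.uniform(1.3, 2.0))
            f_B_max = float(rng.uniform(1.3, 2.0))
        elif mode == "repressive":
            f_A_max = 1.0
            f_B_max = float(rng.uniform(2.0, 4.0))
        else:
            f_A_max = float(rng.uniform(2.0, 4.0))
            f_B_max = float(rng.uniform(2.0, 4.0))
        truth.enhancer_mode[name] = mode
        truth.enhancer_params[name] = {"f_A_max": f_A_max, "f_B_max": f_B_max}
        for dose_A in _REPORTER_DOSES:
            for dose_B in _REPORTER_DOSES:
                mean = reporter_condition_mean(
                    mode, f_A_max, f_B_max, dose_A, dose_B,
                    config.synergy_gamma, config.repression_kappa,
                )
                for rep in range(config.n_reporter_replicates):
                    renilla = (
                        float(np.exp(rng.normal(0.0, sigma_renilla)))
                        if sigma > 0
                        else 1.0
                    )
                    ratio_noise = (
                        float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                    )
                    rows.append(
                        {
                            "enhancer": name,
                            "dose_A_ng": dose_A,
                            "dose_B_ng": dose_B,
                            "replicate": rep + 1,
                            "activity_firefly": mean * ratio_noise * renilla,
                            "activity_renilla": renilla,
                        }
                    )
    return pd.DataFrame(rows), truth


def simulate_all(config: SimulationConfig) -> dict:
    """Run all three simulations on a shared layout and merged truth."""
    layout = build_layout(config)
    genes, truth = layout
    chip, fragments, _ = simulate_chip_experiment(config, layout)
    expr, gene_ids, _ = simulate_expression_timecourse(config, layout)
    reporters, rep_truth = simulate_reporter_assays(config)
    truth.enhancer_mode = rep_truth.enhancer_mode
    truth.enhancer_params = rep_truth.enhancer_params
    return {
        "config": config,
        "genes": genes,
        "truth": truth,
        "chip": chip,
        "fragments": fragments,
        "expression": expr,
        "gene_ids": gene_ids,
        "reporters": reporters,
    }


def write_fixture_bundle(outputs: dict, directory: str | Path) -> dict:
    """Write a simulated study to disk as plain-text fixtures.

    Emits BED6 fragments and truth regions, GFF3 gene models, TSV
    matrices and reporter tables, a JSON truth file and a manifest with
    the seed and per-file SHA-256 digests. Re-running with the same
    seed reproduces byte-identical files.
    """
    from . import pipeline_io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config: SimulationConfig = outputs["config"]
    truth: GroundTruth = outputs["truth"]

    pio.write_fragments_bed(outputs["fragments"], directory / "fragments.bed")
    for factor in ("A", "B"):
        sites = truth.sites_for(factor)
        pio.write_sites_bed(sites, directory / f"truth_regions_{factor}.bed")
        pio.write_matrix_tsv(
            outputs["chip"][factor].data,
            directory / f"chip_{factor}.tsv",
            index_name="fragment",
        )
    pio.write_genes_gff3(outputs["genes"], directory / "genes.gff3")
    pio.write_annotation_tsv(outputs["genes"], directory / "annotations.tsv")

    gene_ids = outputs["gene_ids"]
    for mutant, tensor in outputs["expression"].items():
        cols = {}
        for t in range(tensor.shape[1]):
            for r in range(tensor.shape[2]):
                cols[f"{mutant}_t{t + 1}_rep{r + 1}"] = tensor[:, t, r]
        df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
        pio.write_matrix_tsv(df, directory / f"expression_{mutant}.tsv", index_name="gene")

    outputs["reporters"].to_csv(directory / "reporters.tsv", sep="\t", index=False)

    with open(directory / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)

    files = sorted(
        p.name
        for p in directory.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
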
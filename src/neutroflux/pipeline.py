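"""End-to-end orchestration: simulate -> normalize -> de -> enrich -> score.

Every run writes a self-contained directory with all stage outputs, the
resolved configuration, and a manifest of row counts and checksums so that
reruns with the same seed are verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from neutroflux import __version__
from neutroflux.de import (
    CONTRASTS,
    call_de,
    contrast_table,
    cross_contrast_regression,
    extreme_changes,
    group_medians,
    overlap_percentage,
    venn_partition,
)
from neutroflux.enrichment import enrich
from neutroflux.errors import ConfigError, IntegrityError
from neutroflux.io_formats import (
    GeneSetCollection,
    read_annotation,
    read_design,
    read_gmt,
    read_matrix,
    read_phenotypes,
    read_spot_tables,
    write_matrix,
)
from neutroflux.normalization import normalize_pipeline, pca_qc
from neutroflux.response import correlate_response_with_phenotype, response_score
from neutroflux.synthetic import default_config, simulate_experiment, write_experiment

logger = logging.getLogger(__name__)

STAGE_FILES = [
    "matrix.tsv",
    "qc.tsv",
    "contrasts.tsv",
    "venn.tsv",
    "enrichment.tsv",
    "scores.tsv",
    "correlation.json",
    "manifest.json",
]


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    n_per_group: int = 5
    n_genes: int = 2000
    # optional pre-existing inputs; when unset the experiment is simulated
    spots: str | None = None
    design: str | None = None
    annotation: str | None = None
    phenotypes: str | None = None
    gmt: str | None = None
    threshold: float = 1.5
    strict: bool = True
    pool_channels: str = "all"
    reference_mode: str = "deviation"
    enrichment_method: str = "fisher"
    min_set: int = 3
    score_gene_list: str = "union"  # union | A | B | C
    marker: str = "m1dg"
    correlation_method: str = "spearman"

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ConfigError(f"threshold must be > 1, got {self.threshold}")
        if self.score_gene_list not in ("union", "A", "B", "C"):
            raise ConfigError("score_gene_list must be one of union, A, B, C")
        paths = [self.spots, self.design, self.annotation, self.phenotypes]
        if any(paths) and not all(paths):
            raise ConfigError(
                "provide spots, design, annotation and phenotypes together, "
                "or none of them to simulate"
            )
        for path in paths + [self.gmt]:
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def default_gene_sets(config=None) -> GeneSetCollection:
    """Small synthetic GMT aligned with the simulator's effect blocks."""
    if config is None:
        config = default_config()
    blocks = {
        "shared_up_response": ("induced in both LPS groups", "UpAB"),
        "shared_down_response": ("repressed in both LPS groups", "DnAB"),
        "pmn_specific_up": ("induced only with neutrophils", "UpA"),
        "depletion_specific_up": ("induced only without neutrophils", "UpB"),
        "lps_discriminating": ("separates the two LPS groups", "DiffC"),
    }
    collection = GeneSetCollection()
    for name, (description, prefix) in blocks.items():
        members = [g for g in config.effect_table if g.startswith(prefix)]
        if name == "lps_discriminating":
            members.append("Retnlg")
        if members:
            collection.add(name, description, members)
    # null sets drawn deterministically from the null block
    nulls = [f"Null{i + 1:05d}" for i in range(config.n_genes - len(config.effect_table))]
    for i in range(3):
        members = nulls[i * 40 : (i + 1) * 40]
        if members:
            collection.add(f"null_set_{i + 1}", "no expected enrichment", members)
    return collection


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    stage = "inputs"
    try:
        if config.spots is None:
            sim_config = default_config(
                seed=config.seed,
                n_per_group=config.n_per_group,
                n_genes=config.n_genes,
            )
            experiment = simulate_experiment(sim_config)
            write_experiment(experiment, out_dir / "inputs")
            spots, design = experiment.spots, experiment.design
            annotation, phenotypes = experiment.annotation, experiment.phenotypes
        else:
            spots = read_spot_tables(config.spots)
            design = read_design(config.design)
            annotation = read_annotation(config.annotation)
            phenotypes = read_phenotypes(config.phenotypes)
        gene_sets = read_gmt(config.gmt) if config.gmt else default_gene_sets(
            default_config(seed=config.seed, n_per_group=config.n_per_group,
                           n_genes=config.n_genes)
            if config.spots is None else None
        )
        if gene_sets is None:
            gene_sets = GeneSetCollection()
        manifest["stages"][stage] = {
            "n_spot_records": len(spots),
            "n_samples": len(design),
            "n_gene_sets": len(gene_sets),
        }

        stage = "normalize"
        matrix = normalize_pipeline(
            spots, annotation, pool=config.pool_channels,
            reference_mode=config.reference_mode,
        )
        write_matrix(matrix, out_dir / "matrix.tsv")
        qc = pca_qc(matrix, design)
        qc_frame = qc.scores.copy()
        qc_frame["group_dispersion"] = qc_frame["group"].map(qc.group_dispersion)
        qc_frame["flagged_group"] = qc.flagged_group
        qc_frame.to_csv(out_dir / "qc.tsv", sep="\t", index=False, float_format="%.12g")
        manifest["stages"][stage] = {
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "flagged_group": qc.flagged_group,
        }

        stage = "de"
        medians = group_medians(matrix, design)
        table = contrast_table(medians)
        flags, counts = call_de(table, threshold=config.threshold, strict=config.strict)
        wide = pd.DataFrame(index=matrix.index)
        for contrast, frame in table.items():
            first, second = CONTRASTS[contrast]
            wide[f"{contrast}_log_ratio({first}-{second})"] = frame["log_ratio"]
            wide[f"{contrast}_fold_change"] = frame["fold_change"]
            wide[f"{contrast}_direction"] = frame["direction"]
            wide[f"{contrast}_de"] = flags[contrast]
        wide.index.name = "gene_symbol"
        wide.to_csv(out_dir / "contrasts.tsv", sep="\t", float_format="%.12g")
        venn = venn_partition(flags["A"], flags["B"], flags["C"])
        venn_frame = pd.DataFrame(
            {
                "region": list(venn.members),
                "count": [len(v) for v in venn.members.values()],
                "genes": [",".join(v) for v in venn.members.values()],
            }
        )
        venn_frame.to_csv(out_dir / "venn.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "counts": counts.to_dict(orient="index"),
            "venn": venn.counts,
            "union": venn.union_count,
        }

        stage = "enrich"
        union_genes = venn.union
        universe = list(matrix.index)
        if union_genes and len(gene_sets):
            enrichment = enrich(
                union_genes, universe, gene_sets,
                method=config.enrichment_method, min_set=config.min_set,
            )
        else:
            enrichment = pd.DataFrame(
                columns=["set_name", "K", "k", "n", "N", "p", "q", "overlap"]
            )
        out = enrichment.copy()
        out["overlap"] = out["overlap"].apply(lambda genes: ",".join(genes))
        out.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"][stage] = {"n_sets_tested": int(len(enrichment))}

        stage = "score"
        if config.score_gene_list == "union":
            score_genes = union_genes
        else:
            contrast_flags = flags[config.score_gene_list]
            score_genes = sorted(contrast_flags.index[contrast_flags])
        scores = response_score(matrix, score_genes, design)
        score_frame = pd.DataFrame(
            {
                "sample_id": scores.scores.index,
                "group": [design.groups[s] for s in scores.scores.index],
                "score": scores.scores.to_numpy(),
            }
        )
        score_frame.to_csv(out_dir / "scores.tsv", sep="\t", index=False,
                           float_format="%.12g")
        report = correlate_response_with_phenotype(
            scores, phenotypes, marker=config.marker, method=config.correlation_method
        )
        correlation = {
            "marker": report.marker,
            "method": report.method,
            "statistic": report.statistic,
            "p_value": report.p_value,
            "n": report.n,
        }
        with open(out_dir / "correlation.json", "w") as handle:
            json.dump(correlation, handle, indent=2, sort_keys=True)
            handle.write("\n")
        manifest["stages"][stage] = {
            "n_score_genes": len(score_genes),
            "statistic": report.statistic,
        }
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "config.yaml", "w") as handle:
        yaml.safe_dump(dataclasses.asdict(config), handle, sort_keys=True)
    checksums = {
        name: _sha256(out_dir / name)
        for name in STAGE_FILES
        if name != "manifest.json" and (out_dir / name).exists()
    }
    manifest["checksums"] = checksums
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    summarize(out_dir)
    return out_dir


def summarize(run_dir: str | Path) -> Path:
    """Regenerate the human-readable report from stage outputs alone."""
    run_dir = Path(run_dir)
    for name in ("contrasts.tsv", "venn.tsv", "scores.tsv", "correlation.json"):
        if not (run_dir / name).exists():
            raise IntegrityError(f"missing stage output: {name}")
    contrasts = pd.read_csv(run_dir / "contrasts.tsv", sep="\t", index_col=0)
    venn = pd.read_csv(run_dir / "venn.tsv", sep="\t", keep_default_na=False)
    with open(run_dir / "correlation.json") as handle:
        correlation = json.load(handle)

    members = {
        row["region"]: set(filter(None, str(row["genes"]).split(",")))
        for _, row in venn.iterrows()
    }
    sets = {}
    for letter in "ABC":
        sets[letter] = set()
        for region, genes in members.items():
            if letter in region.replace("_only", ""):
                sets[letter] |= genes
    union = set().union(*members.values()) if members else set()

    lines = ["# Pipeline summary", "", "## Differential expression", ""]
    lines.append("| contrast | groups | DE | up | down |")
    lines.append("|---|---|---|---|---|")
    for contrast, (first, second) in CONTRASTS.items():
        de_col = f"{contrast}_de"
        dir_col = f"{contrast}_direction"
        de = contrasts[de_col]
        up = int((de & (contrasts[dir_col] == "up")).sum())
        down = int((de & (contrasts[dir_col] == "down")).sum())
        lines.append(
            f"| {contrast} | {first} vs {second} | {int(de.sum())} | {up} | {down} |"
        )
    lines += ["", "## Venn partition", ""]
    lines.append("| region | count |")
    lines.append("|---|---|")
    for _, row in venn.iterrows():
        lines.append(f"| {row['region']} | {row['count']} |")
    lines.append(f"| union | {len(union)} |")
    if sets["B"]:
        pct_b_in_a = overlap_percentage(sets["B"], sets["A"])
        lines.append(f"\nOverlap of B within A: {pct_b_in_a}%")
    if sets["C"]:
        pct_c_in_ab = overlap_percentage(sets["C"], sets["A"] | sets["B"])
        lines.append(f"\nOverlap of C within A union B: {pct_c_in_ab}%")

    enrichment_path = run_dir / "enrichment.tsv"
    if enrichment_path.exists():
        enrichment = pd.read_csv(enrichment_path, sep="\t")
        if len(enrichment) and union:
            lines += ["", "## Top enriched sets", ""]
            lines.append("| set | K | k | p | q |")
            lines.append("|---|---|---|---|---|")
            for _, row in enrichment.head(5).iterrows():
                lines.append(
                    f"| {row['set_name']} | {row['K']} | {row['k']} "
                    f"| {row['p']:.3g} | {row['q']:.3g} |"
                )
    lines += ["", "## Response correlation", ""]
    lines.append(
        f"{correlation['method']} correlation of response scores with "
        f"{correlation['marker']}: statistic = {correlation['statistic']:.4f}, "
        f"p = {correlation['p_value']:.4g}, n = {correlation['n']}"
    )
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
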
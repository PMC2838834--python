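"""Synthetic two-colour common-reference experiment generator.

Emulates a 3-group (SHAM, LPS_PMN, LPS_NOPMN) x n mice study on two-channel
spotted arrays where every sample channel is hybridized against one pooled
sham reference. A single per-animal response factor scales both the
expression effects and the genotoxicity phenotype, producing the
expression-response/phenotype coupling the analysis is designed to detect.

Generative model (natural-log scale):

1. per gene g: baseline ``b_g ~ Normal(baseline_log_mean, baseline_log_sd)``
2. per animal a in group G: response factor ``alpha_a`` drawn from a
   mean-one log-normal with dispersion ``animal_heterogeneity_sd``
   (``alpha == 1`` for SHAM)
3. true log-expression ``x_{g,a} = b_g + alpha_a * effect_{g,G}``
4. sample channel spot signal ``exp(x_{g,a} + shift_a + eps_spot)``
5. reference channel spot signal ``exp(b_g + refshift_a + eps_ref)`` —
   the pooled reference shares ``b_g`` across all arrays
6. phenotypes coupled to ``alpha_a`` (see :func:`simulate_phenotypes`)

Unless disabled, each effect spot is accompanied by three unannotated
"balancer" spots whose baselines/effects mirror it (baselines ``b+eA``,
``b+eB``, ``b+eA+eB`` with the corresponding effect signs flipped). These
make every channel's value multiset identical in the noise-free case, so
quantile normalization — whose working assumption is that all channels share
one intensity distribution — is exactly distribution-preserving there and
injected fold changes survive the pipeline unchanged. Balancer spots carry
no gene symbol and are dropped at the gene-collapse step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from neutroflux.errors import ConfigError
from neutroflux.io_formats import (
    GROUP_LABELS,
    PhenotypeTable,
    SpotTable,
    StudyDesign,
    write_annotation,
    write_design,
    write_phenotypes,
    write_spot_table,
)


class Effect(NamedTuple):
    """True natural-log fold change of a gene in the two LPS contrasts."""

    lps_pmn: float
    lps_nopmn: float


class GroupParam(NamedTuple):
    """Mean/SD of a phenotype marker per group; mean None = below detection."""

    mean: float | None
    sd: float


@dataclass
class SimulationConfig:
    n_per_group: int = 5
    n_genes: int = 2000
    spots_per_gene: int = 2
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.0
    effect_table: dict[str, Effect] = field(default_factory=dict)
    animal_heterogeneity_sd: float = 0.3
    spot_noise_sd: float = 0.10
    array_shift_sd: float = 0.20
    reference_noise_sd: float = 0.05
    control_spot_fraction: float = 0.01
    balancer_spots: bool = True
    # phenotype parameters, per group
    mpo_balf: dict[str, GroupParam] = field(
        default_factory=lambda: {
            "SHAM": GroupParam(None, 0.0),
            "LPS_PMN": GroupParam(81.4, 20.5),
            "LPS_NOPMN": GroupParam(None, 0.0),
        }
    )
    mpo_lung: dict[str, GroupParam] = field(
        default_factory=lambda: {
            "SHAM": GroupParam(58.18, 77.26),
            "LPS_PMN": GroupParam(145.99, 94.82),
            "LPS_NOPMN": GroupParam(58.18, 77.26),
        }
    )
    m1dg: dict[str, GroupParam] = field(
        default_factory=lambda: {
            "SHAM": GroupParam(5.1, 0.2),
            "LPS_PMN": GroupParam(13.6, 2.8),
            "LPS_NOPMN": GroupParam(10.6, 2.5),
        }
    )
    m1dg_response_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("animal_heterogeneity_sd", "spot_noise_sd", "array_shift_sd",
                     "reference_noise_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for table in (self.mpo_balf, self.mpo_lung, self.m1dg):
            for group, param in table.items():
                if group not in GROUP_LABELS:
                    raise ConfigError(f"unknown group {group!r} in phenotype parameters")
                if param.sd < 0:
                    raise ConfigError("phenotype sds must be >= 0")
                if param.mean is not None and param.mean <= 0:
                    raise ConfigError("phenotype group means must be > 0")
        for group in GROUP_LABELS:
            if group not in self.m1dg:
                raise ConfigError(f"m1dg parameters missing group {group}")

    def noise_free(self) -> "SimulationConfig":
        """Copy with every noise term and the heterogeneity set to zero."""
        return replace(
            self,
            animal_heterogeneity_sd=0.0,
            spot_noise_sd=0.0,
            array_shift_sd=0.0,
            reference_noise_sd=0.0,
        )


@dataclass
class SimulationTruth:
    """Ground truth: per-gene baselines/effects and per-animal factors."""

    genes: pd.DataFrame    # gene_symbol, baseline, effect_lps_pmn, effect_lps_nopmn
    animals: pd.DataFrame  # sample_id, group, alpha, sample_shift, reference_shift


@dataclass
class SimulatedExperiment:
    spots: SpotTable
    design: StudyDesign
    annotation: pd.DataFrame
    phenotypes: PhenotypeTable
    truth: SimulationTruth


def default_config(**overrides) -> SimulationConfig:
    """Study-calibrated defaults.

    The effect table pins the four named genes to their reported extreme
    fold changes (Saa3 up 15x / 7.7x, Pon1 down 2.6x, Krt1-15 down 2.7x,
    Retnlg separating only the two LPS groups at 2x) and adds generic
    blocks covering every region of the three-way DE Venn diagram, plus a
    null majority.
    """
    effects: dict[str, Effect] = {
        "Saa3": Effect(math.log(15.0), math.log(7.7)),
        "Pon1": Effect(-math.log(2.6), 0.0),
        "Krt1-15": Effect(0.0, -math.log(2.7)),
        "Retnlg": Effect(0.5 * math.log(2.0), -0.5 * math.log(2.0)),
    }
    # shared response, attenuated without neutrophils; below the 1.5x
    # between-LPS threshold so these genes stay out of contrast C
    for i in range(150):
        effects[f"UpAB{i + 1:03d}"] = Effect(math.log(2.5), math.log(1.8))
    for i in range(40):
        effects[f"DnAB{i + 1:03d}"] = Effect(-math.log(2.2), -math.log(1.8))
    # group-specific response
    for i in range(60):
        effects[f"UpA{i + 1:03d}"] = Effect(math.log(1.9), math.log(1.35))
    for i in range(20):
        effects[f"UpB{i + 1:03d}"] = Effect(math.log(1.35), math.log(1.9))
    # genes separating the two LPS groups without clearing either
    # versus-sham threshold (11 generic + Retnlg = 12)
    for i in range(11):
        effects[f"DiffC{i + 1:03d}"] = Effect(0.5 * math.log(2.0), -0.5 * math.log(2.0))
    return SimulationConfig(effect_table=effects, **overrides)


def _gene_symbols(config: SimulationConfig) -> list[str]:
    named = list(config.effect_table)
    if config.n_genes < len(named):
        raise ConfigError(
            f"n_genes={config.n_genes} smaller than effect table ({len(named)} genes)"
        )
    nulls = [f"Null{i + 1:05d}" for i in range(config.n_genes - len(named))]
    return named + nulls


def _mean_one_lognormal(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """Log-normal response factors with expectation exactly 1."""
    if sd == 0:
        return np.ones(n)
    return rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=n)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, low: float = 0.0
) -> np.ndarray:
    """Rejection-sampled Normal(mean, sd) conditioned on > low."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def simulate_phenotypes(
    config: SimulationConfig,
    groups: "pd.Series | dict[str, str]",
    alphas: "pd.Series | dict[str, float] | None" = None,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Draw per-animal phenotype markers for the given sample -> group map.

    ``m1dg = sham_mean + coupling * alpha * (group_mean - sham_mean) + noise``
    truncated > 0; MPO markers are group-level draws truncated at 0, with
    below-detection groups reported as missing. ``alphas`` defaults to 1
    for every animal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = pd.Series(dict(groups) if isinstance(groups, dict) else groups)
    if alphas is None:
        alphas = pd.Series(1.0, index=groups.index)
    else:
        alphas = pd.Series(dict(alphas) if isinstance(alphas, dict) else alphas)
    sham_m1dg = config.m1dg["SHAM"].mean
    rows = []
    for sample_id, group in groups.items():
        alpha = float(alphas[sample_id])
        balf = config.mpo_balf[group]
        lung = config.mpo_lung[group]
        m1 = config.m1dg[group]
        mpo_balf = (
            np.nan if balf.mean is None
            else float(_truncated_normal(rng, balf.mean, balf.sd, 1)[0])
        )
        mpo_lung = (
            np.nan if lung.mean is None
            else float(_truncated_normal(rng, lung.mean, lung.sd, 1)[0])
        )
        loc = sham_m1dg + config.m1dg_response_coupling * alpha * (m1.mean - sham_m1dg)
        m1dg = float(_truncated_normal(rng, loc, m1.sd, 1)[0]) if m1.sd > 0 else max(loc, 1e-12)
        rows.append((sample_id, mpo_balf, mpo_lung, m1dg))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=PhenotypeTable.COLUMNS)
    )


def _balancer_frame(base: pd.DataFrame) -> pd.DataFrame:
    """Three mirrored unannotated probes per effect probe.

    For an effect probe (b, eA, eB) the quadruple
    ``{(b, +eA, +eB), (b+eA, -eA, +eB), (b+eB, +eA, -eB), (b+eA+eB, -eA, -eB)}``
    produces, in each sample channel, exactly the multiset of its four
    baselines — so noise-free channels are permutations of one another.
    """
    eff = base[(base["eA"] != 0) | (base["eB"] != 0)]
    mirrors = []
    for tag, db, sa, sb in (
        ("ba", "eA", -1.0, 1.0),
        ("bb", "eB", 1.0, -1.0),
        ("bc", None, -1.0, -1.0),
    ):
        m = eff.copy()
        m["probe_id"] = m["probe_id"] + "_" + tag
        m["gene_symbol"] = ""
        shift = m["eA"] + m["eB"] if db is None else m[db]
        m["baseline"] = m["baseline"] + shift
        m["eA"] = sa * m["eA"]
        m["eB"] = sb * m["eB"]
        mirrors.append(m)
    return pd.concat(mirrors, ignore_index=True)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one full synthetic experiment; same config -> identical output."""
    rng = np.random.default_rng(config.seed)
    symbols = _gene_symbols(config)
    n_genes = len(symbols)
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    eff_a = np.array([config.effect_table.get(g, Effect(0.0, 0.0)).lps_pmn for g in symbols])
    eff_b = np.array([config.effect_table.get(g, Effect(0.0, 0.0)).lps_nopmn for g in symbols])

    # probe-level layout: spots_per_gene identical probes per gene
    probes = pd.DataFrame(
        {
            "probe_id": [
                f"P{i + 1:05d}_{k + 1}"
                for i in range(n_genes)
                for k in range(config.spots_per_gene)
            ],
            "gene_symbol": np.repeat(symbols, config.spots_per_gene),
            "baseline": np.repeat(baselines, config.spots_per_gene),
            "eA": np.repeat(eff_a, config.spots_per_gene),
            "eB": np.repeat(eff_b, config.spots_per_gene),
        }
    )
    if config.balancer_spots:
        probes = pd.concat([probes, _balancer_frame(probes)], ignore_index=True)
    probes["spot_kind"] = "regular"

    # control spots: half negative near the signal floor, half positive at a
    # fixed high level; base values shared across arrays like gene baselines
    n_controls = int(round(config.control_spot_fraction * n_genes * config.spots_per_gene))
    n_neg = n_controls // 2
    neg = pd.DataFrame(
        {
            "probe_id": [f"NEG{i + 1:04d}" for i in range(n_neg)],
            "gene_symbol": "",
            "baseline": np.log(rng.uniform(1.0, 3.0, n_neg)),
            "eA": 0.0,
            "eB": 0.0,
            "spot_kind": "negative_control",
        }
    )
    pos = pd.DataFrame(
        {
            "probe_id": [f"POS{i + 1:04d}" for i in range(n_controls - n_neg)],
            "gene_symbol": "",
            "baseline": 12.0,
            "eA": 0.0,
            "eB": 0.0,
            "spot_kind": "positive_control",
        }
    )
    layout = pd.concat([probes, neg, pos], ignore_index=True)
    layout["spot_id"] = [f"S{i + 1:06d}" for i in range(len(layout))]

    # animals
    sample_ids, group_of = [], {}
    for group, prefix in zip(GROUP_LABELS, ("sham", "lps_pmn", "lps_nopmn")):
        for i in range(config.n_per_group):
            sid = f"{prefix}_{i + 1}"
            sample_ids.append(sid)
            group_of[sid] = group
    design = StudyDesign(group_of)
    alphas = {}
    for sid in sample_ids:
        if group_of[sid] == "SHAM":
            alphas[sid] = 1.0
        else:
            alphas[sid] = float(
                _mean_one_lognormal(rng, config.animal_heterogeneity_sd, 1)[0]
            )
    sample_shifts = {s: float(rng.normal(0, config.array_shift_sd)) for s in sample_ids}
    ref_shifts = {s: float(rng.normal(0, config.array_shift_sd)) for s in sample_ids}

    base = layout["baseline"].to_numpy()
    effect_of_group = {
        "SHAM": np.zeros(len(layout)),
        "LPS_PMN": layout["eA"].to_numpy(),
        "LPS_NOPMN": layout["eB"].to_numpy(),
    }
    frames = []
    for sid in sample_ids:
        group = group_of[sid]
        x = base + alphas[sid] * effect_of_group[group]
        eps = rng.normal(0, config.spot_noise_sd, len(layout)) if config.spot_noise_sd else 0.0
        eps_ref = (
            rng.normal(0, config.reference_noise_sd, len(layout))
            if config.reference_noise_sd else 0.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "array_id": sid,
                    "spot_id": layout["spot_id"],
                    "probe_id": layout["probe_id"],
                    "gene_symbol": layout["gene_symbol"],
                    "spot_kind": layout["spot_kind"],
                    "sample_signal": np.exp(x + sample_shifts[sid] + eps),
                    "reference_signal": np.exp(base + ref_shifts[sid] + eps_ref),
                }
            )
        )
    spots = SpotTable(pd.concat(frames, ignore_index=True))

    annotation = layout.loc[layout["spot_kind"] == "regular", ["probe_id", "gene_symbol"]]
    annotation = annotation.reset_index(drop=True)

    phenotypes = simulate_phenotypes(config, group_of, alphas, rng=rng)

    truth = SimulationTruth(
        genes=pd.DataFrame(
            {
                "gene_symbol": symbols,
                "baseline": baselines,
                "effect_lps_pmn": eff_a,
                "effect_lps_nopmn": eff_b,
            }
        ),
        animals=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": [group_of[s] for s in sample_ids],
                "alpha": [alphas[s] for s in sample_ids],
                "sample_shift": [sample_shifts[s] for s in sample_ids],
                "reference_shift": [ref_shifts[s] for s in sample_ids],
            }
        ),
    )
    return SimulatedExperiment(spots, design, annotation, phenotypes, truth)


def write_experiment(experiment: SimulatedExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Write spot_tables.tsv, design.tsv, annotation.tsv, phenotypes.tsv, truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.tsv"
             for name in ("spot_tables", "design", "annotation", "phenotypes", "truth")}
    write_spot_table(experiment.spots, paths["spot_tables"])
    write_design(experiment.design, paths["design"])
    write_annotation(experiment.annotation, paths["annotation"])
    write_phenotypes(experiment.phenotypes, paths["phenotypes"])
    truth_genes = experiment.truth.genes.assign(record="gene")
    truth_animals = experiment.truth.animals.assign(record="animal")
    pd.concat([truth_genes, truth_animals], ignore_index=True).to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.12g"
    )
    return paths
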
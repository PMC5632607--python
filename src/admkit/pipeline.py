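"""End-to-end study pipeline on synthetic landscapes.

Mirrors the full workflow: environmental layers -> virtual species ->
museum-style sampling -> ENFA suitability -> cross-engine pseudoabsences ->
dual threshold selection -> binary PDM -> habitat-masked ADM -> simulated
field survey -> site and buffer validation -> stacked richness.  Every stage
is a pure function of (config, seed); the resolved configuration is logged
with each run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .enfa import EnfaSuitability
from .envelopes import PercentileEnvelope
from .evaluation import (
    ThresholdReport,
    binarize,
    metric_curve,
    sample_pseudoabsences,
    select_kappa_threshold,
    select_roc_threshold,
    wilcoxon_signed_rank,
)
from .errors import StratificationError
from .grids import BinaryModel, HabitatTable
from .habitat import area_summary, reduce_to_adm
from .occurrences import OccurrenceSet, train_test_split
from .richness import stack_richness
from .validation import ValidationReport, batch_validate, proportionality_test

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Declarative configuration of a synthetic study run."""

    # landscape
    n_layers: int = 6
    n_rows: int = 100
    n_cols: int = 100
    autocorr_range: float = 8.0
    n_latent: int = 3
    idiosyncratic: float = 0.35
    cell_size: float = 1000.0
    # virtual species (one entry per species)
    species_names: list[str] = dc_field(default_factory=lambda: ["sp1", "sp2", "sp3"])
    marginality_targets: list[float] = dc_field(default_factory=lambda: [1.0, 1.2, 1.5])
    tolerance_targets: list[float] = dc_field(default_factory=lambda: [0.5, 0.5, 0.5])
    n_museum: list[int] = dc_field(default_factory=lambda: [120, 120, 120])
    sampling_gamma: float = 2.0
    clustering: float = 0.0
    # land cover / habitat
    n_classes: int = 4
    patch_scale: float = 4.0
    subcell_ratio: int = 4
    suitable_classes: list[int] = dc_field(default_factory=lambda: [1])
    suitable_fraction: float = 0.5
    # evaluation
    test_fraction: float = 0.25
    thresholds: list[float] | None = None
    threshold_rule: str = "kappa"  # kappa | roc
    pseudoabsence_engine_threshold: float = 5.0
    # field survey
    n_sites: int = 46
    points_per_site: int = 30
    min_point_spacing: float = 200.0
    detection_prob: float = 0.8
    buffer_radius: float = 1000.0

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpeciesResult:
    species: str
    model: EnfaSuitability
    report: ThresholdReport
    pdm: BinaryModel
    adm: BinaryModel
    field_occurrences: "object"


@dataclass
class StudyResult:
    config: StudyConfig
    seed: int
    species: list[SpeciesResult]
    validation: ValidationReport
    richness: "object"
    wilcoxon: tuple[float, float] | None
    proportionality: tuple[float, float] | None


def _seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2^31 derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_study(seed: int, config: StudyConfig | None = None) -> StudyResult:
    """Run the complete synthetic study once; deterministic in (config, seed)."""
    cfg = config or StudyConfig()
    log.info("study run: seed=%d config=%s", seed, json.dumps(cfg.to_dict()))
    n_sp = len(cfg.species_names)
    seeds = _seeds(seed, 2 + 4 * n_sp)
    stack = synthetic.gen_env_stack(
        seeds[0], cfg.n_layers, cfg.n_rows, cfg.n_cols, cfg.autocorr_range,
        cfg.n_latent, cfg.idiosyncratic, cfg.cell_size,
    )
    lc = synthetic.gen_landcover(
        stack, seeds[1], cfg.n_classes, cfg.patch_scale, cfg.subcell_ratio
    )
    habitat = HabitatTable(
        {name: frozenset(cfg.suitable_classes) for name in cfg.species_names}
    )

    results: list[SpeciesResult] = []
    field_sets = []
    museum_counts = []
    for i, name in enumerate(cfg.species_names):
        s_vs, s_occ, s_pa, s_survey = seeds[2 + 4 * i : 6 + 4 * i]
        vs = synthetic.gen_virtual_species(
            stack, s_vs, cfg.marginality_targets[i], cfg.tolerance_targets[i],
            frozenset(cfg.suitable_classes), species=name,
        )
        museum = synthetic.sample_occurrences(
            vs, cfg.n_museum[i], s_occ, clustering=cfg.clustering,
            gamma=cfg.sampling_gamma,
        )
        train, test = train_test_split(museum, cfg.test_fraction, seed=s_occ)

        model = EnfaSuitability().fit(stack, train)
        suit = model.predict(stack)

        # cross-engine design: the envelope engine's predicted absence area
        # supplies the pseudoabsences for testing the ENFA model
        other = PercentileEnvelope().fit(stack, train).predict(stack)
        other_binary = binarize(other, cfg.pseudoabsence_engine_threshold, "external")
        n_test_cells = len(test.distinct_cells(stack.geometry))
        pseudo = sample_pseudoabsences(
            other_binary, n_test_cells, s_pa, exclusion=museum, engine_under_test="enfa"
        )

        report = metric_curve(suit, test, pseudo, cfg.thresholds)
        t_kappa = select_kappa_threshold(report)
        t_roc = select_roc_threshold(report)
        t = t_kappa if cfg.threshold_rule == "kappa" else t_roc
        pdm = binarize(suit, t, cfg.threshold_rule)
        adm = reduce_to_adm(pdm, lc, habitat, name, cfg.suitable_fraction)

        try:
            field = synthetic.simulate_field_survey(
                vs, lc, cfg.n_sites, cfg.points_per_site, cfg.min_point_spacing,
                cfg.detection_prob, s_survey,
            )
        except StratificationError as exc:
            # a species whose niche misses the surveyable habitat cannot be
            # field-validated; keep its models, record an empty survey
            log.warning("%s not surveyable: %s", name, exc)
            field = OccurrenceSet(name, np.empty((0, 2)), "field")
        results.append(SpeciesResult(name, model, report, pdm, adm, field))
        field_sets.append(field)
        museum_counts.append(len(museum))

    validation = batch_validate([r.adm for r in results], field_sets, cfg.buffer_radius)
    richness = stack_richness([r.adm for r in results])

    wilc = None
    pairs = [(r.report.kappa_threshold, r.report.roc_threshold) for r in results]
    if any(a != b for a, b in pairs):
        wilc = wilcoxon_signed_rank(pairs)

    prop = None
    field_cell_counts = [
        len(f.distinct_cells(stack.geometry)) for f in field_sets
    ]
    if n_sp >= 3 and np.std(museum_counts) > 0 and np.std(field_cell_counts) > 0:
        prop = proportionality_test(museum_counts, field_cell_counts)

    return StudyResult(cfg, seed, results, validation, richness, wilc, prop)


def study_summary(result: StudyResult) -> dict:
    """Flat JSON-serializable summary of one study run."""
    rows = result.validation.rows
    per_species = []
    for r, (_, vrow) in zip(result.species, rows.iterrows()):
        per_species.append(
            {
                "species": r.species,
                "global_marginality": r.model.global_marginality_,
                "global_tolerance": r.model.global_tolerance_,
                "auc": r.report.auc,
                "kappa_threshold": r.report.kappa_threshold,
                "roc_threshold": r.report.roc_threshold,
                "pdm_cells": area_summary(r.pdm)["presence_cells"],
                "adm_cells": area_summary(r.adm)["presence_cells"],
                "site_success_pct": vrow["site_success_pct"],
                "buffer_success_pct": vrow["buffer_success_pct"],
            }
        )
    return {
        "seed": result.seed,
        "species": per_species,
        "validation_summary": result.validation.summary,
        "wilcoxon": result.wilcoxon,
        "proportionality": result.proportionality,
        "max_richness": int(result.richness.grid.max()),
    }
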
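"""Orchestration of the four pipeline stages.

prepare → enumerate driving coordinates → growing-string product search per
driving set → trivial-pathway filtering → NEB with band harvesting →
TS validation → relabeling at the refinement level → per-reaction
subsampling → hierarchical dataset. Execution is single-process and
deterministic for a fixed seed and the built-in analytic potentials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .calculators import CalculatorError, MorseCluster, MuellerBrown, PotentialModel
from .core import Geometry, canonical_graph_key, hill_formula, perceive_bonds
from .database import (
    ReactionRecord,
    deduplicate_structures,
    relabel_structures,
    subsample_per_reaction,
    write_database,
)
from .driving import enumerate_driving_coordinates
from .filters import FilterReason, filter_pathway, is_feasible_structure, validate_ts
from .gsm import GSMParams, PathStatus, TriadExtractionError, extract_triad, run_se_gsm
from .neb import Band, HarvestState, NEBParams, run_neb
from .nms import NMSConfig, normal_mode_sample
from .prep import prepare_reactant
from .toys import refined_morse_cluster

__all__ = ["RunConfig", "StageReport", "RunReport", "build_model", "run_pipeline", "run_nms"]

logger = logging.getLogger(__name__)

_MODEL_REGISTRY = {
    "morse": lambda: MorseCluster(),
    "morse-refined": refined_morse_cluster,
    "mueller-brown": MuellerBrown,
}


def build_model(spec: str | PotentialModel) -> PotentialModel:
    if isinstance(spec, PotentialModel):
        return spec
    try:
        return _MODEL_REGISTRY[spec]()
    except KeyError:
        raise ValueError(
            f"unknown model spec {spec!r}; available: {sorted(_MODEL_REGISTRY)}"
        ) from None


@dataclass
class RunConfig:
    """Structured configuration of one sampling run."""

    reactants: list = field(default_factory=list)  # SMILES, XYZ paths or Geometry
    sampling_model: str | PotentialModel = "morse"
    refinement_model: str | PotentialModel = "morse-refined"
    output: str = "dataset.h5"
    seed: int = 0
    max_break: int = 2
    max_form: int = 2
    heavy_only: bool = False
    perception_scale: float = 1.2
    flat_threshold: float = 0.1  # eV, trivial-pathway gate
    harvest_threshold: float = 0.1  # eV/Å, cumulative-Fmax band sampling
    subsample_n: int = 1000  # structures kept per reaction
    reactant_fmax: float = 0.01
    gsm: GSMParams = field(default_factory=GSMParams)
    neb: NEBParams = field(default_factory=NEBParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gsm = GSMParams(**raw.pop("gsm", {}))
        neb = NEBParams(**raw.pop("neb", {}))
        return cls(gsm=gsm, neb=neb, **raw)


@dataclass
class StageReport:
    attempted: int = 0
    succeeded: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def conserved(self) -> bool:
        return self.attempted == self.succeeded + self.n_rejected


@dataclass
class RunReport:
    seed: int
    stages: dict[str, StageReport] = field(default_factory=dict)
    n_records: int = 0
    n_structures: int = 0
    warnings: list[str] = field(default_factory=list)

    def stage(self, name: str) -> StageReport:
        return self.stages.setdefault(name, StageReport())

    def summary(self) -> str:
        lines = [f"seed: {self.seed}"]
        for name, st in self.stages.items():
            rej = ", ".join(f"{k}={v}" for k, v in sorted(st.rejected.items()))
            lines.append(
                f"{name}: {st.succeeded}/{st.attempted} succeeded"
                + (f" ({rej})" if rej else "")
            )
        lines.append(f"dataset: {self.n_records} reactions, {self.n_structures} structures")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _reaction_structures(harvest: HarvestState) -> list[Geometry]:
    out: list[Geometry] = []
    for _, images in harvest.harvested:
        out.extend(images)
    return deduplicate_structures(out)


def run_pipeline(config: RunConfig) -> tuple[Path, RunReport]:
    """Execute the full sampling protocol; returns (dataset path, report)."""
    sampling = build_model(config.sampling_model)
    refinement = build_model(config.refinement_model)
    report = RunReport(seed=config.seed)
    records: list[ReactionRecord] = []
    rid_counter = 0

    for r_idx, source in enumerate(config.reactants):
        prep_stage = report.stage("prepare")
        prep_stage.attempted += 1
        try:
            opt = prepare_reactant(
                source, sampling, fmax_tol=config.reactant_fmax, seed=config.seed + r_idx
            )
        except (CalculatorError, RuntimeError, ValueError) as exc:
            prep_stage.reject("prep-failed")
            report.warnings.append(f"reactant {r_idx}: preparation failed ({exc})")
            continue
        if not opt.converged:
            prep_stage.reject("non-convergent")
            continue
        prep_stage.succeeded += 1
        reactant = opt.geometry
        r_graph = perceive_bonds(reactant, config.perception_scale)
        r_key = canonical_graph_key(r_graph)

        driving_sets = enumerate_driving_coordinates(
            r_graph,
            max_break=config.max_break,
            max_form=config.max_form,
            heavy_only=config.heavy_only,
        )
        enum_stage = report.stage("enumerate")
        enum_stage.attempted += len(driving_sets)
        enum_stage.succeeded += len(driving_sets)

        seen_products: set[str] = set()
        for d_idx, driving in enumerate(driving_sets):
            gsm_stage = report.stage("gsm")
            gsm_stage.attempted += 1
            try:
                path = run_se_gsm(reactant, driving, sampling, config.gsm)
                triad = extract_triad(path, sampling, config.gsm)
            except TriadExtractionError as exc:
                gsm_stage.reject(exc.status.value)
                continue
            except CalculatorError:
                gsm_stage.reject(PathStatus.FAILED_CALCULATOR.value)
                continue
            gsm_stage.succeeded += 1

            filt_stage = report.stage("filter")
            filt_stage.attempted += 1
            p_graph = perceive_bonds(triad.product, config.perception_scale)
            verdict = filter_pathway(
                path.energies + [triad.product.energy],
                r_graph,
                p_graph,
                seen_product_keys=seen_products,
                flat_threshold=config.flat_threshold,
            )
            if verdict.accepted:
                for g, graph in ((triad.reactant, r_graph), (triad.ts, None), (triad.product, p_graph)):
                    v = is_feasible_structure(g, graph, perception_scale=config.perception_scale)
                    if not v.accepted:
                        verdict = v
                        break
            if not verdict.accepted:
                filt_stage.reject(verdict.reason.value)
                continue
            filt_stage.succeeded += 1
            seen_products.add(canonical_graph_key(p_graph))

            neb_stage = report.stage("neb")
            neb_stage.attempted += 1
            harvest = HarvestState(threshold=config.harvest_threshold)
            try:
                band, harvest = run_neb(
                    triad,
                    sampling,
                    fmax_tol=config.neb.fmax_tol,
                    max_steps=config.neb.max_steps,
                    harvest=harvest,
                    params=config.neb,
                )
            except CalculatorError:
                neb_stage.reject(FilterReason.NON_CONVERGENT.value)
                continue
            if not band.converged:
                neb_stage.reject(FilterReason.NON_CONVERGENT.value)
                continue
            neb_stage.succeeded += 1

            ts_stage = report.stage("ts-validation")
            ts_stage.attempted += 1
            energies = band.energies
            ts_image = band.images[1 + int(np.argmax(energies[1:-1]))]
            v = validate_ts(ts_image, sampling)
            if not v.accepted:
                ts_stage.reject(v.reason.value)
                continue
            ts_stage.succeeded += 1

            structures = _reaction_structures(harvest)
            refine_stage = report.stage("refine")
            refine_stage.attempted += len(structures)
            structures = relabel_structures(structures, refinement)
            refine_stage.succeeded += len(structures)
            for _ in range(refine_stage.attempted - refine_stage.succeeded):
                refine_stage.reject("calculator-failure")
            structures = subsample_per_reaction(
                structures, n=config.subsample_n,
                seed=(config.seed * 100003 + rid_counter) % (2**31),
            )
            if not structures:
                continue
            records.append(
                ReactionRecord(
                    formula=hill_formula(structures[0]),
                    reaction_id=f"{rid_counter:04d}",
                    structures=structures,
                    provenance={
                        "reactant_key": r_key,
                        "driving": "; ".join(
                            f"{c.kind.value} {c.pair[0] + 1} {c.pair[1] + 1}"
                            for c in driving.changes
                        ),
                        "n_harvested_bands": len(harvest.harvested),
                    },
                )
            )
            rid_counter += 1

    out = Path(config.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    write_database(records, out)
    report.n_records = len(records)
    report.n_structures = sum(r.n_structures for r in records)
    if not records:
        report.warnings.append("empty final dataset: every pathway was filtered out")
    for name, st in report.stages.items():
        assert st.conserved(), f"stage {name} miscounts its outcomes"
    return out, report


def run_nms(
    reactants: list,
    model: str | PotentialModel = "morse",
    refinement: str | PotentialModel | None = None,
    config: NMSConfig = NMSConfig(),
    output: str = "nms_dataset.h5",
    reactant_fmax: float = 0.01,
) -> tuple[Path, RunReport]:
    """Normal-mode-sampling baseline dataset over the same reactants."""
    sampling = build_model(model)
    high = build_model(refinement) if refinement is not None else None
    report = RunReport(seed=config.seed)
    records: list[ReactionRecord] = []
    for r_idx, source in enumerate(reactants):
        stage = report.stage("nms")
        stage.attempted += 1
        try:
            opt = prepare_reactant(source, sampling, fmax_tol=reactant_fmax, seed=config.seed + r_idx)
            samples = normal_mode_sample(
                opt.geometry,
                sampling,
                config=NMSConfig(
                    temperature=config.temperature,
                    n_samples=config.n_samples,
                    seed=(config.seed * 99991 + r_idx) % (2**31),
                    min_fmax=max(config.min_fmax, reactant_fmax),
                ),
            )
        except (CalculatorError, ValueError, RuntimeError) as exc:
            stage.reject("failed")
            report.warnings.append(f"reactant {r_idx}: {exc}")
            continue
        labeled = relabel_structures(samples, high or sampling)
        stage.succeeded += 1
        records.append(
            ReactionRecord(
                formula=hill_formula(labeled[0]),
                reaction_id=f"nms{r_idx:04d}",
                structures=labeled,
                provenance={"method": "nms", "temperature_K": config.temperature},
            )
        )
    out = Path(output)
    out.parent.mkdir(parents=True, exist_ok=True)
    write_database(records, out)
    report.n_records = len(records)
    report.n_structures = sum(r.n_structures for r in records)
    return out, report
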
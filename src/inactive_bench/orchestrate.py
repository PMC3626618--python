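"""End-to-end experiment orchestration from a single config.

``run_experiment`` wires the stages together: universe generation (or
loading real libraries), decoy building, cell assembly over the plan grid,
training the classifier roster, metric evaluation, and export with full
provenance.  Reruns with the same config reproduce the grid TSV
byte-identically for native classifiers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .assembly import ExperimentPlan, PlanContext, SetComposition, parse_source
from .chem import CompoundLibrary, MoleculeRecord, read_library, write_library
from .decoys import DecoyConfig, MatchWindow, build_dud_library
from .metrics import EvaluationGrid, compute_metrics, confusion
from .models import NATIVE_CLASSIFIERS, registered_adapters, train_classifier
from .universe import Universe, UniverseParams, generate_universe

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIERS: dict[str, dict] = {
    "naive_bayes": {},
    "knn": {"k": 1},
    "hyperpipes": {},
}


@dataclass
class RunConfig:
    """Validated configuration of one full experiment run."""

    universe: UniverseParams
    decoys: DecoyConfig
    plan: ExperimentPlan
    classifiers: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_CLASSIFIERS))
    library_paths: Optional[dict[str, str]] = None
    save_datasets: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        known = set(NATIVE_CLASSIFIERS) | set(registered_adapters())
        unknown = [name for name in self.classifiers if name not in known]
        if unknown:
            raise ValueError(
                f"unknown classifier(s) {unknown}; native: {list(NATIVE_CLASSIFIERS)}, "
                f"registered adapters: {list(registered_adapters()) or 'none'}"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        uni = UniverseParams(**raw.get("universe", {}))
        decoy_raw = dict(raw.get("decoys", {}))
        relaxed = decoy_raw.pop("relaxed", False)
        window_kwargs = {k: decoy_raw.pop(k) for k in ("rel_tol", "abs_tol")
                         if k in decoy_raw}
        window = MatchWindow.relaxed() if relaxed else MatchWindow(**window_kwargs)
        decoys = DecoyConfig(window=window, **decoy_raw)
        plan_raw = dict(raw.get("plan", {}))
        comp = SetComposition(**plan_raw.pop("composition"))
        sources = tuple(plan_raw.pop("sources"))
        plan = ExperimentPlan(mode=plan_raw.pop("mode"), inactive_sources=sources,
                              composition=comp, **plan_raw)
        return cls(
            universe=uni, decoys=decoys, plan=plan,
            classifiers=raw.get("classifiers", dict(DEFAULT_CLASSIFIERS)),
            library_paths=raw.get("libraries"),
            save_datasets=raw.get("save_datasets", False),
            log_level=raw.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def fingerprint_tag(n_bits: int) -> str:
    return f"synthetic-{n_bits}"


def run_grid(plan: ExperimentPlan, universe: Universe,
             dud_library: Optional[CompoundLibrary] = None,
             classifiers: Optional[dict[str, dict]] = None,
             context: Optional[PlanContext] = None) -> EvaluationGrid:
    """Train and evaluate every (source, iteration, classifier) cell of a plan."""
    classifiers = classifiers or dict(DEFAULT_CLASSIFIERS)
    if context is None:
        context = PlanContext(plan, universe, dud_library)
    tag = fingerprint_tag(universe.params.n_bits)
    grid = EvaluationGrid()
    for source in plan.inactive_sources:
        for iteration in range(plan.effective_iterations(source)):
            train, test = context.cell(source, iteration)
            for name, hyper in classifiers.items():
                model = train_classifier(name, train, **hyper)
                result = compute_metrics(confusion(model.predict(test), test.labels))
                if result.undefined:
                    logger.info("undefined metrics %s for %s/%s/iter%d",
                                sorted(result.undefined), name, source, iteration)
                grid.add(name, source, tag, plan.mode, iteration, result)
    return grid


def _config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(
        {
            "universe": asdict(config.universe),
            "decoys": asdict(config.decoys),
            "plan": asdict(config.plan),
            "classifiers": config.classifiers,
            "libraries": config.library_paths,
        },
        sort_keys=True,
    )
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_or_generate_universe(config: RunConfig) -> Universe:
    if config.library_paths:
        paths = config.library_paths
        n_bits = config.universe.n_bits
        libs = {}
        for key in ("actives", "zinc_like", "mddr_like"):
            if key not in paths:
                raise ValueError(f"libraries config missing {key!r}")
            libs[key] = read_library(paths[key], source=key, n_bits=n_bits)
        return Universe(actives=libs["actives"], zinc_like=libs["zinc_like"],
                        mddr_like=libs["mddr_like"], params=config.universe,
                        meta={"loaded_from": dict(paths)})
    return generate_universe(config.universe)


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes ``grid.tsv``, ``decoy_report.tsv`` (when decoys are built),
    ``provenance.yaml`` and ``run.log``; with ``save_datasets`` also every
    assembled dataset as a labelled CSV library.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("inactive_bench")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "universe"
    try:
        universe = _load_or_generate_universe(config)
        logger.info("universe ready: %d actives, %d zinc_like, %d mddr_like",
                    len(universe.actives), len(universe.zinc_like),
                    len(universe.mddr_like))

        dud_library = None
        shortfalls = 0
        needs_dud = any(parse_source(s)[0] == "dud" for s in config.plan.inactive_sources)
        if needs_dud:
            stage = "decoy_generation"
            dud_library, report = build_dud_library(universe.actives,
                                                    universe.zinc_like, config.decoys)
            shortfalls = int((report["shortfall"] > 0).sum())
            report.to_csv(out / "decoy_report.tsv", sep="\t", index=False)
            logger.info("decoy library: %d records, %d ligands with shortfall",
                        len(dud_library), shortfalls)

        stage = "assembly"
        context = PlanContext(config.plan, universe, dud_library)
        if config.save_datasets:
            for source in config.plan.inactive_sources:
                for iteration in range(config.plan.effective_iterations(source)):
                    train, test = context.cell(source, iteration)
                    for ds in (train, test):
                        labelled = [
                            MoleculeRecord(id=r.id, structure=r.structure,
                                           descriptors=r.descriptors,
                                           fingerprint=r.fingerprint,
                                           scaffold=r.scaffold, activity=bool(lab))
                            for r, lab in ds.items()
                        ]
                        write_library(CompoundLibrary("custom", labelled),
                                      out / "datasets" /
                                      f"{source}_iter{iteration}_{ds.split}.csv")

        stage = "evaluation"
        grid = run_grid(config.plan, universe, dud_library, config.classifiers,
                        context=context)
        grid.export(out / "grid.tsv")

        stage = "provenance"
        provenance = {
            "config_hash": _config_hash(config),
            "base_seed": config.plan.base_seed,
            "universe_seed": config.universe.seed,
            "library_sizes": {name: len(lib) for name, lib in universe.pools().items()},
            "dud_library_size": None if dud_library is None else len(dud_library),
            "ligands_with_shortfall": shortfalls,
            "classifiers": config.classifiers,
            "mode": config.plan.mode,
            "sources": list(config.plan.inactive_sources),
            "iterations": config.plan.iterations,
        }
        with open(out / "provenance.yaml", "w") as fh:
            yaml.safe_dump(provenance, fh, sort_keys=True)
    except Exception as exc:
        logger.error("run aborted in stage %s: %s", stage, exc)
        (out / "INCOMPLETE").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
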
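"""Dataset serialization, round-trip readers, and the three-dataset pipeline.

Population datasets export either as a CSV bundle of normalized tables
(patients, attributes, conditions, encounters, procedures, observations) or
as JSON-lines with one full person record per line; cohorts export as a
single analysis-ready CSV.  Every export writes a manifest with record counts
and per-file SHA-256 checksums, and every reader verifies them.

``run_pipeline`` chains the full workflow: population-prevalence run,
enriched-prevalence run, age/sex-matched cohort draw, and the validation
report — each stage seeded, logged and resumable from its manifest.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .cohort import (
    CohortDataset,
    CohortRecord,
    draw_cohort,
    max_feasible_cohort,
    pool_case_counts,
    registry_cohort_target,
)
from .engine import (
    EngineContext,
    Event,
    PersonRecord,
    PopulationDataset,
    SimulationConfig,
    generate_population,
    week_to_date,
)
from .larynx import larynx_actions, load_shipped_module
from .registry import FIVE_YEAR_SURVIVAL_BY_UICC, default_bundle
from .validation import frequency_compare

__all__ = [
    "DatasetManifest",
    "export_dataset",
    "read_population_dataset",
    "read_cohort_dataset",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("larynxsim")


@dataclass
class DatasetManifest:
    label: str
    kind: str                      # population | cohort
    format: str                    # csv-bundle | jsonl | csv
    seed: int
    counts: dict[str, int]
    config: dict = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256

    def write(self, out_dir: Path) -> None:
        (out_dir / "manifest.json").write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def read(cls, out_dir: Path) -> "DatasetManifest":
        raw = json.loads((out_dir / "manifest.json").read_text())
        return cls(**raw)

    def verify(self, out_dir: Path) -> bool:
        for name, digest in self.files.items():
            path = out_dir / name
            if not path.exists() or _sha256(path) != digest:
                return False
        return True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# population export
# ---------------------------------------------------------------------------

_PATIENT_HEADER = ["person_id", "sex", "birth_date", "death_date", "alive"]
_EVENT_TABLES = {"condition": "conditions.csv", "encounter": "encounters.csv",
                 "procedure": "procedures.csv", "observation": "observations.csv"}


def _person_rows(person: PersonRecord, target_week: int):
    alive = person.alive_at(target_week)
    death = "" if person.death_week is None else week_to_date(person.death_week).isoformat()
    return [person.id, person.sex, week_to_date(person.birth_week).isoformat(), death, str(alive).lower()]


def _public_attributes(person: PersonRecord) -> dict:
    return {k: v for k, v in person.attributes.items() if not k.startswith("_")}


def export_dataset(
    ds: PopulationDataset | CohortDataset,
    out_dir: str | Path,
    format: str = "csv-bundle",
    label: str = "dataset",
) -> DatasetManifest:
    """Serialize a dataset and write its manifest alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(ds, CohortDataset):
        return _export_cohort(ds, out, label)
    if format == "jsonl":
        return _export_population_jsonl(ds, out, label)
    if format == "csv-bundle":
        return _export_population_csv(ds, out, label)
    raise ValueError(f"unknown format {format!r}")


def _population_counts(ds: PopulationDataset) -> dict[str, int]:
    diseased = sum(1 for p in ds.all_records() if any(k.startswith("diagnosis_week::") for k in p.attributes))
    return {"alive": len(ds.alive), "deceased": len(ds.deceased),
            "total": len(ds.alive) + len(ds.deceased), "diseased": diseased}


def _export_population_csv(ds: PopulationDataset, out: Path, label: str) -> DatasetManifest:
    target = ds.config.target_week
    files = ["patients.csv", "attributes.csv", *_EVENT_TABLES.values()]
    writers = {}
    handles = {}
    for name in files:
        handles[name] = (out / name).open("w", newline="")
        writers[name] = csv.writer(handles[name])
    writers["patients.csv"].writerow(_PATIENT_HEADER)
    writers["attributes.csv"].writerow(["person_id", "key", "value"])
    for table in _EVENT_TABLES.values():
        writers[table].writerow(["person_id", "date", "week", "label", "code", "detail"])
    for person in ds.all_records():
        writers["patients.csv"].writerow(_person_rows(person, target))
        for k, v in sorted(_public_attributes(person).items()):
            writers["attributes.csv"].writerow([person.id, k, v])
        for ev in person.events:
            writers[_EVENT_TABLES[ev.kind]].writerow(
                [person.id, week_to_date(ev.week).isoformat(), ev.week, ev.label, ev.code, ev.detail])
    for h in handles.values():
        h.close()
    manifest = DatasetManifest(
        label, "population", "csv-bundle", ds.seed, _population_counts(ds),
        config=_config_echo(ds.config), files={name: _sha256(out / name) for name in files},
    )
    manifest.write(out)
    return manifest


def _export_population_jsonl(ds: PopulationDataset, out: Path, label: str) -> DatasetManifest:
    path = out / "records.jsonl"
    with path.open("w") as fh:
        for person in ds.all_records():
            fh.write(json.dumps({
                "id": person.id, "sex": person.sex, "birth_week": person.birth_week,
                "death_week": person.death_week,
                "attributes": _public_attributes(person),
                "events": [list(ev) for ev in person.events],
            }, sort_keys=True) + "\n")
    manifest = DatasetManifest(
        label, "population", "jsonl", ds.seed, _population_counts(ds),
        config=_config_echo(ds.config), files={"records.jsonl": _sha256(path)},
    )
    manifest.write(out)
    return manifest


def _export_cohort(ds: CohortDataset, out: Path, label: str) -> DatasetManifest:
    path = out / "cohort.csv"
    fields = [f.name for f in dataclasses.fields(CohortRecord)]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for rec in ds.records:
            w.writerow([getattr(rec, f) for f in fields])
    manifest = DatasetManifest(
        label, "cohort", "csv", ds.seed,
        {"records": len(ds.records), "events": sum(r.event for r in ds.records)},
        config={"target_week": ds.target_week},
        files={"cohort.csv": _sha256(path)},
    )
    manifest.write(out)
    return manifest


def _config_echo(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_population_dataset(out_dir: str | Path) -> PopulationDataset:
    """Re-read an exported population dataset (either format), verifying checksums."""
    out = Path(out_dir)
    manifest = DatasetManifest.read(out)
    if not manifest.verify(out):
        raise ValueError(f"checksum verification failed in {out}")
    config = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in manifest.config.items()})
    persons: dict[str, PersonRecord] = {}
    if manifest.format == "jsonl":
        for line in (out / "records.jsonl").read_text().splitlines():
            raw = json.loads(line)
            p = PersonRecord(raw["id"], raw["sex"], raw["birth_week"], raw["death_week"],
                             dict(raw["attributes"]), [Event(*ev) for ev in raw["events"]])
            persons[p.id] = p
    else:
        import datetime

        from .engine import date_to_week

        with (out / "patients.csv").open() as fh:
            for row in csv.DictReader(fh):
                death = row["death_date"]
                persons[row["person_id"]] = PersonRecord(
                    row["person_id"], row["sex"],
                    date_to_week(datetime.date.fromisoformat(row["birth_date"])),
                    date_to_week(datetime.date.fromisoformat(death)) if death else None,
                )
        with (out / "attributes.csv").open() as fh:
            for row in csv.DictReader(fh):
                persons[row["person_id"]].attributes[row["key"]] = _parse_attr(row["value"])
        for kind, name in _EVENT_TABLES.items():
            with (out / name).open() as fh:
                for row in csv.DictReader(fh):
                    persons[row["person_id"]].events.append(
                        Event(int(row["week"]), kind, row["label"], row["code"], row["detail"]))
        for p in persons.values():
            p.events.sort(key=lambda e: (e.week, e.kind, e.label))
    alive = [p for p in persons.values() if p.alive_at(config.target_week)]
    deceased = [p for p in persons.values() if not p.alive_at(config.target_week)]
    counts = {"alive": len(alive), "deceased": len(deceased)}
    for key, n in counts.items():
        if manifest.counts.get(key) != n:
            raise ValueError(f"manifest count mismatch for {key}: {manifest.counts.get(key)} != {n}")
    return PopulationDataset(alive, deceased, config, (), manifest.seed)


def _parse_attr(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value in ("True", "False"):
        return value == "True"
    return value


def read_cohort_dataset(out_dir: str | Path) -> CohortDataset:
    out = Path(out_dir)
    manifest = DatasetManifest.read(out)
    if not manifest.verify(out):
        raise ValueError(f"checksum verification failed in {out}")
    records = []
    with (out / "cohort.csv").open() as fh:
        for row in csv.DictReader(fh):
            records.append(CohortRecord(
                person_id=row["person_id"], sex=row["sex"], age_group=row["age_group"],
                age_at_diagnosis=float(row["age_at_diagnosis"]), diagnosis_week=int(row["diagnosis_week"]),
                T=row["T"], N=row["N"], M=row["M"], UICC=row["UICC"], grading=row["grading"],
                ecog=int(row["ecog"]), localization=row["localization"],
                initial_treatment=row["initial_treatment"], neck_dissection=row["neck_dissection"],
                r_status=row["r_status"], adjuvant=row["adjuvant"],
                followup_weeks=int(row["followup_weeks"]), event=row["event"] == "True",
            ))
    if manifest.counts.get("records") != len(records):
        raise ValueError("manifest count mismatch for cohort records")
    return CohortDataset(records, {}, manifest.seed, manifest.config["target_week"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    prevalence_alive: int = 100_000
    enriched_alive: int = 50_000
    enrichment_factor: float = 300.0
    alpha: float = 0.01
    plot: bool = False


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, DatasetManifest | None]:
    """Prevalence run, enriched run, cohort draw and validation, end to end.

    Each stage is seeded from the pipeline seed, logged, and skipped when its
    manifest already verifies (resumability).  Returns the stage manifests.
    """
    out = Path(config.out_dir)
    bundle = default_bundle()
    module = load_shipped_module()
    manifests: dict[str, DatasetManifest | None] = {}

    def stage(name: str, fn):
        stage_dir = out / name
        if (stage_dir / "manifest.json").exists():
            try:
                manifest = DatasetManifest.read(stage_dir)
                if manifest.verify(stage_dir):
                    log.info("stage %s: reusing existing export", name)
                    return manifest, True
            except Exception:
                pass
        try:
            return fn(stage_dir), False
        except Exception as exc:  # noqa: BLE001 - halt with the stage named
            raise PipelineError(name, exc) from exc

    def gen_prevalence(stage_dir: Path):
        cfg = SimulationConfig(mode="prevalence", target_alive=config.prevalence_alive,
                               seed=config.seed)
        ctx = EngineContext(bundle=bundle, actions=larynx_actions())
        ds = generate_population(cfg, [module], ctx)
        log.info("prevalence: %d alive, %d deceased", len(ds.alive), len(ds.deceased))
        return export_dataset(ds, stage_dir, "csv-bundle", label="population-prevalence")

    def gen_enriched(stage_dir: Path):
        cfg = SimulationConfig(mode="enriched", target_alive=config.enriched_alive,
                               seed=config.seed + 1, enrichment_factor=config.enrichment_factor)
        ctx = EngineContext(bundle=bundle, actions=larynx_actions())
        ds = generate_population(cfg, [module], ctx)
        log.info("enriched: %d alive, %d deceased", len(ds.alive), len(ds.deceased))
        export = export_dataset(ds, stage_dir, "csv-bundle", label="enriched-prevalence")
        # keep the in-memory pool for the cohort stage
        gen_enriched.dataset = ds
        return export

    manifests["prevalence"], _ = stage("prevalence", gen_prevalence)
    manifests["enriched"], reused = stage("enriched", gen_enriched)
    pool = getattr(gen_enriched, "dataset", None)
    if pool is None:
        pool = read_population_dataset(out / "enriched")

    def gen_cohort(stage_dir: Path):
        target = registry_cohort_target()
        counts = pool_case_counts(pool)
        n, quotas = max_feasible_cohort(counts, target)
        log.info("cohort: pool supports N=%d at the registry mix", n)
        cohort = draw_cohort(pool, quotas, seed=config.seed + 2)
        gen_cohort.dataset = cohort
        return export_dataset(cohort, stage_dir, label="cohort-matched")

    manifests["cohort"], _ = stage("cohort", gen_cohort)
    cohort = getattr(gen_cohort, "dataset", None)
    if cohort is None:
        cohort = read_cohort_dataset(out / "cohort")

    def run_validation(stage_dir: Path):
        stage_dir.mkdir(parents=True, exist_ok=True)
        report = frequency_compare(cohort, bundle, alpha=config.alpha, seed=config.seed + 3)
        (stage_dir / "report.json").write_text(report.to_json())
        (stage_dir / "report.txt").write_text(report.to_text())
        if config.plot:
            report.plot_km(str(stage_dir / "km_by_stage.png"), cohort,
                           reference_anchors=FIVE_YEAR_SURVIVAL_BY_UICC)
        log.info("validation: %d comparison(s) flagged at %.0f%%", report.n_flagged, 100 * config.alpha)
        run_validation.report = report
        return None

    manifests["validation"], _ = stage("validation", lambda d: (run_validation(d), None)[1])
    manifests["validation_report"] = getattr(run_validation, "report", None)
    return manifests
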
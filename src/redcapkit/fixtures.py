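"""Seeded synthetic REDCap projects with planted discrepancies.

``generate`` writes the three export CSVs (records, dictionary, event-form
mapping) in exactly the dialects the readers expect, plus a JSON manifest
describing every planted discrepancy. The default project shape is a small
multicenter longitudinal study: a baseline visit with Demographics and
Comorbidities forms (fields like ``age`` and ``copd``), a follow-up event,
and hospital DAGs.

All randomness flows from one ``random.Random(seed)`` (MT19937, stable
across platforms); the same spec and seed produce byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, ValidationError
from .logic import EvalContext, evaluate, parse_source
from .project_io import FieldDef, ValidationSpec, write_dictionary

__all__ = ["FixtureSpec", "ManifestEntry", "FixtureManifest", "generate", "snapshot_fix"]

AGE_CALC = "rounddown(datediff([dob],[visit_date],'y'))"
DEFAULT_EVENTS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("baseline_visit_arm_1", ("identification", "demographics", "comorbidities")),
    ("follow_up_arm_1", ("follow_up",)),
)


@dataclass
class FixtureSpec:
    n_records: int = 20
    seed: int = 0
    dags: tuple[str, ...] = ("hospital_5", "hospital_11", "hospital_24")
    events: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_EVENTS
    # planted discrepancies
    missing_required: Mapping[str, int] = dc_field(default_factory=dict)  # field -> count
    out_of_range: Mapping[str, int] = dc_field(default_factory=dict)  # field -> count
    n_calc_mismatch: int = 0  # stored age perturbed by +1
    n_missing_events: int = 0  # records whose follow-up row is dropped
    n_checkbox_no_branching: int = 0  # extra checkbox fields without branching


@dataclass(frozen=True)
class ManifestEntry:
    kind: str  # missing | out_of_range | calc_mismatch | missing_event
    record_id: str
    event: str
    field: str
    original: str
    perturbed: str


@dataclass
class FixtureManifest:
    entries: list[ManifestEntry] = dc_field(default_factory=list)

    def of_kind(self, kind: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.kind == kind]

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.entries], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        return cls([ManifestEntry(**item) for item in json.loads(text)])


# ---------------------------------------------------------------------------


def _build_dictionary(spec: FixtureSpec) -> list[FieldDef]:
    date = ValidationSpec(kind="date_ymd")
    fields = [
        FieldDef("record_id", "identification", "text", "Record ID"),
        FieldDef("dob", "demographics", "text", "Date of birth", validation=date),
        FieldDef("visit_date", "demographics", "text", "Visit date", validation=date),
        FieldDef("age", "demographics", "calc", "Age", calculation=AGE_CALC),
        FieldDef("sex", "demographics", "radio", "Sex",
                 choices={"1": "Female", "2": "Male"}),
        FieldDef("weight", "demographics", "text", "Weight (kg)",
                 validation=ValidationSpec(kind="number", min="30", max="250")),
        FieldDef("has_comorb", "comorbidities", "yesno", "Any comorbidity"),
        FieldDef("copd", "comorbidities", "yesno",
                 "Chronic obstructive pulmonary disease"),
        FieldDef("comorb", "comorbidities", "checkbox", "Comorbidities",
                 choices={"1": "Hypertension", "2": "Diabetes", "3": "Chronic kidney disease"},
                 branching_logic="[has_comorb] = '1'"),
    ]
    for i in range(spec.n_checkbox_no_branching):
        fields.append(
            FieldDef(f"symptoms_{i + 1}", "comorbidities", "checkbox",
                     f"Symptom set {i + 1}",
                     choices={"1": "Fever", "2": "Cough"})
        )
    fields += [
        FieldDef("status", "follow_up", "radio", "Vital status",
                 choices={"1": "Alive", "2": "Dead"}),
        FieldDef("oxygen_sat", "follow_up", "text", "Oxygen saturation (%)",
                 validation=ValidationSpec(kind="number", min="50", max="100")),
    ]
    return fields


def _compute_age(dob: str, visit: str) -> str:
    value = evaluate(parse_source(AGE_CALC),
                     EvalContext(row={"dob": dob, "visit_date": visit}))
    return str(int(value))


def _field_event(field_name: str, dictionary: Sequence[FieldDef],
                 spec: FixtureSpec) -> str:
    form = next(f.form for f in dictionary if f.name == field_name)
    for event, forms in spec.events:
        if form in forms:
            return event
    raise ConfigError(f"form {form!r} is mapped to no event in the fixture spec")


def generate(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write records.csv / dictionary.csv / events.csv / manifest.json."""
    rng = random.Random(spec.seed)
    dictionary = _build_dictionary(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    baseline_event = spec.events[0][0]
    followup_event = spec.events[1][0] if len(spec.events) > 1 else None

    # record ids like "100-58": the numeric prefix identifies the site
    site_numbers: list[set[int]] = [set() for _ in spec.dags]
    records: list[dict] = []
    for _ in range(spec.n_records):
        site = rng.randrange(len(spec.dags))
        number = rng.randrange(10, 10 + 20 * max(spec.n_records, 10))
        while number in site_numbers[site]:
            number = rng.randrange(10, 10 + 20 * max(spec.n_records, 10))
        site_numbers[site].add(number)
        rid = f"{100 + site}-{number}"
        dob = (_dt.date(1940, 1, 1) + _dt.timedelta(days=rng.randrange(22000))).isoformat()
        visit = (_dt.date(2021, 1, 1) + _dt.timedelta(days=rng.randrange(365))).isoformat()
        base = {
            "record_id": rid,
            "redcap_event_name": baseline_event,
            "redcap_data_access_group": spec.dags[site],
            "dob": dob,
            "visit_date": visit,
            "age": _compute_age(dob, visit),
            "sex": rng.choice(["1", "2"]),
            "weight": str(rng.randrange(45, 120)),
            "has_comorb": rng.choice(["0", "1"]),
            "copd": rng.choice(["0", "1"]),
        }
        for code in ("1", "2", "3"):
            base[f"comorb___{code}"] = (
                rng.choice(["0", "1"]) if base["has_comorb"] == "1" else "0"
            )
        for i in range(spec.n_checkbox_no_branching):
            for code in ("1", "2"):
                base[f"symptoms_{i + 1}___{code}"] = rng.choice(["0", "1"])
        base["identification_complete"] = "2"
        base["demographics_complete"] = "2"
        base["comorbidities_complete"] = "2"
        base["comorbidities_timestamp"] = "2021-06-01 10:00:00"
        records.append(base)
        if followup_event is not None:
            records.append({
                "record_id": rid,
                "redcap_event_name": followup_event,
                "redcap_data_access_group": spec.dags[site],
                "status": rng.choice(["1", "2"]),
                "oxygen_sat": str(rng.randrange(85, 100)),
                "follow_up_complete": "2",
            })

    columns = ["record_id", "redcap_event_name", "redcap_data_access_group"]
    for f in dictionary:
        if f.name == "record_id":
            continue
        if f.field_type == "checkbox":
            columns += [f"{f.name}___{c}" for c in f.choices]
        else:
            columns.append(f.name)
    forms = list(dict.fromkeys(f.form for f in dictionary))
    columns += [f"{form}_complete" for form in forms]
    columns.append("comorbidities_timestamp")
    df = pd.DataFrame(records, columns=columns).fillna("")

    manifest = FixtureManifest()
    baseline_rows = df.index[df["redcap_event_name"] == baseline_event].tolist()
    taken: dict[str, set[int]] = {}

    def pick(field_name: str, count: int, pool: list[int]) -> list[int]:
        used = taken.setdefault(field_name, set())
        available = [i for i in pool if i not in used]
        if count > len(available):
            raise ConfigError(
                f"cannot plant {count} discrepancies on {field_name!r}: "
                f"only {len(available)} free cells"
            )
        chosen = sorted(rng.sample(available, count))
        used.update(chosen)
        return chosen

    for field_name, count in spec.missing_required.items():
        event = _field_event(field_name, dictionary, spec)
        pool = df.index[df["redcap_event_name"] == event].tolist()
        for i in pick(field_name, count, pool):
            original = df.at[i, field_name]
            df.at[i, field_name] = ""
            if field_name == "age":
                # keep the recalculation consistent: blank input, blank output
                taken.setdefault("dob", set()).add(i)
                df.at[i, "dob"] = ""
            manifest.entries.append(ManifestEntry(
                "missing", df.at[i, "record_id"], event, field_name, original, ""))

    for field_name, count in spec.out_of_range.items():
        event = _field_event(field_name, dictionary, spec)
        f = next(fd for fd in dictionary if fd.name == field_name)
        if f.validation.max is None:
            raise ConfigError(f"field {field_name!r} has no validation max to violate")
        bad = str(int(float(f.validation.max)) + 50)
        pool = df.index[df["redcap_event_name"] == event].tolist()
        for i in pick(field_name, count, pool):
            original = df.at[i, field_name]
            df.at[i, field_name] = bad
            manifest.entries.append(ManifestEntry(
                "out_of_range", df.at[i, "record_id"], event, field_name, original, bad))

    if spec.n_calc_mismatch:
        for i in pick("age", spec.n_calc_mismatch, baseline_rows):
            original = df.at[i, "age"]
            perturbed = str(int(original) + 1)
            df.at[i, "age"] = perturbed
            manifest.entries.append(ManifestEntry(
                "calc_mismatch", df.at[i, "record_id"], baseline_event,
                "age", original, perturbed))

    dropped_rows: list[int] = []
    if spec.n_missing_events:
        if followup_event is None:
            raise ConfigError("cannot plant missing events in a single-event fixture")
        followup_rows = df.index[df["redcap_event_name"] == followup_event].tolist()
        for i in pick("__event__", spec.n_missing_events, followup_rows):
            dropped_rows.append(i)
            manifest.entries.append(ManifestEntry(
                "missing_event", df.at[i, "record_id"], followup_event, "", "", ""))
    if dropped_rows:
        df = df.drop(index=dropped_rows).reset_index(drop=True)

    df.to_csv(out / "records.csv", index=False, lineterminator="\n")
    write_dictionary(dictionary, out / "dictionary.csv")
    event_rows = [
        {"arm_num": 1, "unique_event_name": event, "form": form}
        for event, event_forms in spec.events
        for form in event_forms
    ]
    pd.DataFrame(event_rows, columns=["arm_num", "unique_event_name", "form"]).to_csv(
        out / "events.csv", index=False, lineterminator="\n"
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------


def snapshot_fix(
    fixture_dir: str | Path,
    manifest: FixtureManifest,
    resolve: Sequence[ManifestEntry] = (),
    miscorrect: Sequence[ManifestEntry] = (),
    out_path: str | Path | None = None,
) -> Path:
    """Produce a follow-up records.csv: ``resolve`` entries get a valid value
    back, ``miscorrect`` entries a different but still-violating one."""
    resolve = list(resolve)
    miscorrect = list(miscorrect)
    if set(map(id, resolve)) & set(map(id, miscorrect)) or (
        set(resolve) & set(miscorrect)
    ):
        raise ValidationError("resolve and miscorrect sets must be disjoint")
    known = set(manifest.entries)
    for entry in [*resolve, *miscorrect]:
        if entry not in known:
            raise ValidationError(f"entry not in manifest: {entry}")

    fixture_dir = Path(fixture_dir)
    df = pd.read_csv(fixture_dir / "records.csv", dtype=str, keep_default_na=False)

    def locate(entry: ManifestEntry) -> int:
        mask = (df["record_id"] == entry.record_id) & (
            df["redcap_event_name"] == entry.event
        )
        hits = df.index[mask].tolist()
        if not hits:
            raise ValidationError(f"no row for {entry.record_id}/{entry.event}")
        return hits[0]

    for entry in resolve:
        if entry.kind == "missing_event":
            row = {c: "" for c in df.columns}
            row.update({
                "record_id": entry.record_id,
                "redcap_event_name": entry.event,
                "status": "1",
                "follow_up_complete": "2",
            })
            dag_rows = df[df["record_id"] == entry.record_id]
            if not dag_rows.empty and "redcap_data_access_group" in df.columns:
                row["redcap_data_access_group"] = dag_rows.iloc[0]["redcap_data_access_group"]
            df.loc[len(df)] = [row.get(c, "") for c in df.columns]
        else:
            df.at[locate(entry), entry.field] = entry.original

    for entry in miscorrect:
        if entry.kind == "missing":
            df.at[locate(entry), entry.field] = "999"
        elif entry.kind == "out_of_range":
            df.at[locate(entry), entry.field] = str(int(float(entry.perturbed)) + 7)
        elif entry.kind == "calc_mismatch":
            df.at[locate(entry), entry.field] = str(int(float(entry.perturbed)) + 2)
        else:
            raise ValidationError(f"cannot miscorrect a {entry.kind!r} entry")

    out_path = Path(out_path) if out_path else fixture_dir / "records_fixed.csv"
    df.to_csv(out_path, index=False, lineterminator="\n")
    return out_path
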
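# redcapkit

Turn raw REDCap project exports into analysis-ready, quality-checked
datasets. The package reads the three standard export CSVs (records, data
dictionary, event-form mapping), runs a five-step transformation with a
human-readable trace, and generates clinical-data-management query reports —
including missing-event detection and longitudinal diffing of two query
snapshots into **New / Pending / Solved / Miscorrected**.

At its core sits a full parser and evaluator for REDCap's branching-logic /
calculated-field expression language with three-valued (Kleene) truth
semantics and REDCap blank rules, used to recalculate calc fields, handle
checkbox missingness, and drive query rules.

## Library quick tour

```python
from redcapkit import (read_project, transform_project, rd_query, rd_event,
                       check_queries, QueryRule, write_report)

bundle = read_project("records.csv", "dictionary.csv", "events.csv")

result = transform_project(bundle)      # 5 steps + trace
print(result.trace_text())              # recalc report, checkbox renames, warnings

report = rd_query(result, QueryRule.missing(["copd", "age"]))
for row in report.summary:              # Table-2-style summary
    print(row)
write_report(report, "queries.csv")

missing = rd_event(bundle, ["follow_up_arm_1"])   # events REDCap didn't export
diff = check_queries(old_report, report)          # New/Pending/Solved/Miscorrected
```

Transformation steps (all traced): 1) recalculate every calc field and
compare with stored values; 2) rename checkbox columns to their option
labels, relabel 0/1 → No/Yes, blank rows whose parent branching logic is
missing; 3) replace raw codes with labels (event/DAG keep both versions);
4) translate branching logic into the updated dictionary; 5) delete
`*_complete` / `*_timestamp` columns. `TransformConfig(final_format=
"by_event")` additionally splits the output per event (or `"by_form"`).

Query rules state the **valid** condition in the same expression syntax;
rows where it evaluates false or missing raise a query. `{var}` in a
broadcast expression substitutes each variable name:

```python
QueryRule(["age"], ["[{var}] <> '' and [{var}] <= 100"])
```

## CLI

```bash
redcapkit fixture --out-dir fx --seed 1 --missing copd=6 --missing age=5
redcapkit transform --data fx/records.csv --dic fx/dictionary.csv --events fx/events.csv --out-dir out
redcapkit query --data fx/records.csv --dic fx/dictionary.csv --events fx/events.csv \
    --var copd --var age --out queries.csv
redcapkit events --data fx/records.csv --dic fx/dictionary.csv --events fx/events.csv \
    --event follow_up_arm_1 --out missing_events.csv
redcapkit check old_queries.csv new_queries.csv --out diff.csv
```

A YAML config (`--config run.yml`) can carry paths, transform options and
declarative rules; flags override it, paths resolve relative to the file.
Exit codes: 0 ok, 2 validation/configuration error, 1 unexpected failure.

`redcapkit.fixtures` generates complete seeded synthetic projects (the three
CSVs plus a JSON manifest) with planted discrepancies — missing required
values, out-of-range values, calc mismatches, missing events — and
`snapshot_fix` derives follow-up snapshots with chosen discrepancies
resolved or miscorrected, for exercising the diff workflow end to end.

Live API import is out of scope by design; work from the exported files.

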
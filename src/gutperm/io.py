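"""File formats used across the pipeline.

Time courses travel as long CSV (animal_id, group, time_h, conc_ng_ml,
censored); model parameters as JSON/YAML blocks with explicit fixed/fitted
lists; frame annotations as JSON lines; animal scores as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from gutperm.cle import FrameAnnotation
from gutperm.pk import PKParameters, TimeCourse

TIMECOURSE_COLUMNS = ["animal_id", "group", "time_h", "conc_ng_ml", "censored"]


def write_timecourses(tcs: list[TimeCourse], path: str | Path) -> None:
    rows = []
    for tc in tcs:
        for t, c, cens in zip(tc.times, tc.concentrations, tc.censored):
            rows.append({"animal_id": tc.animal_id, "group": tc.group,
                         "time_h": t, "conc_ng_ml": c, "censored": int(cens)})
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    df = pd.read_csv(path)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV missing columns: {sorted(missing)}")
    out = []
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("time_h")
        out.append(TimeCourse(
            times=sub["time_h"].to_numpy(),
            concentrations=sub["conc_ng_ml"].to_numpy(),
            censored=sub["censored"].to_numpy().astype(bool),
            animal_id=str(animal),
            group=str(sub["group"].iloc[0]),
        ))
    return out


def write_parameters(params: PKParameters, path: str | Path) -> None:
    path = Path(path)
    payload = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_parameters(path: str | Path) -> PKParameters:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return PKParameters.from_dict(payload)


def write_annotations(cohort: dict[str, list[FrameAnnotation]], path: str | Path) -> None:
    """JSON lines, one object per frame, keyed by animal."""
    with open(path, "w") as fh:
        for animal, frames in cohort.items():
            for i, frame in enumerate(frames):
                rec = {"animal_id": animal, "frame": i, **dataclasses.asdict(frame)}
                fh.write(json.dumps(rec) + "\n")


def read_annotations(path: str | Path) -> dict[str, list[FrameAnnotation]]:
    cohort: dict[str, list[FrameAnnotation]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            animal = rec.pop("animal_id")
            rec.pop("frame", None)
            cohort.setdefault(animal, []).append(FrameAnnotation(**rec))
    return cohort
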
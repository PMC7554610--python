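"""Independent brute-force re-derivation of the lesion classifiers.

Used only by the tests: enumerates every candidate (trigger index,
regression index) pair with naive slicing instead of the running-nadir
scan, so agreement with the package classifier is a genuine dual-route
check.
"""

from __future__ import annotations

import numpy as np

from vrano.records import (
    ClinicalEvent,
    Histology,
    LesionRecord,
    VolumeMeasurement,
)

_HISTOLOGY_STATUS = {
    Histology.TUMOR: "progression",
    Histology.NECROSIS: "radionecrosis",
    Histology.BOTH: "progression_and_radionecrosis",
}


def brute_force_classify(
    record: LesionRecord,
    rel: float = 0.728,
    abs_thr: float = 0.2,
    pr: float = 0.65,
) -> tuple[str, float | None]:
    """(status, event_t) by exhaustive enumeration."""
    ms = sorted(record.measurements, key=lambda m: m.t)
    pre = [m for m in ms if m.t < 0]
    baseline = pre[0].volume
    resections = sorted(
        (e for e in record.events if e.event_type == "resection"), key=lambda e: e.t
    )
    res = resections[0] if resections else None
    post = [m for m in ms if m.t >= 0 and (res is None or m.t <= res.t)]

    trigger_i = None
    trigger_ref = None
    for i in range(len(post)):
        ref = min([baseline] + [post[j].volume for j in range(i)])
        if post[i].volume >= ref * (1 + rel) and post[i].volume - ref >= abs_thr:
            trigger_i, trigger_ref = i, ref
            break

    regressed = False
    if trigger_i is not None:
        for j in range(trigger_i + 1, len(post)):
            treated = any(
                post[k].intervening_treatment for k in range(trigger_i + 1, j + 1)
            )
            if treated:
                continue
            if post[j].volume <= trigger_ref or post[j].volume <= baseline * (1 - pr):
                regressed = True
                break

    if res is not None:
        status = _HISTOLOGY_STATUS[res.histology]
        event_t = post[trigger_i].t if trigger_i is not None else res.t
        return status, event_t
    if trigger_i is None:
        return "controlled", None
    return ("radionecrosis" if regressed else "progression"), post[trigger_i].t


def random_record(rng: np.random.Generator, lesion_id: str = "L") -> LesionRecord:
    """Random short trajectory biased toward threshold boundary cases."""
    n_post = int(rng.integers(1, 8))
    times = np.sort(rng.choice(np.arange(10, 900, 5), size=n_post, replace=False))
    grid = np.round(np.arange(0.05, 3.05, 0.05), 2)
    baseline_v = float(rng.choice(grid))
    measurements = [VolumeMeasurement(t=-8.0, volume=baseline_v)]
    volumes = [baseline_v]
    for i, t in enumerate(times):
        draw = rng.random()
        ref = min(volumes)
        if draw < 0.12:  # exactly at the relative threshold
            v = ref * 1.728
        elif draw < 0.20:  # exactly at the absolute threshold
            v = ref + 0.2
        elif draw < 0.28:  # exactly at the PR regression level
            v = baseline_v * 0.35
        else:
            v = float(rng.choice(grid))
        measurements.append(
            VolumeMeasurement(
                t=float(t),
                volume=v,
                intervening_treatment=bool(rng.random() < 0.2),
            )
        )
        volumes.append(v)
    events = ()
    if rng.random() < 0.12:
        cut = float(rng.choice(times)) + 1.0
        events = (
            ClinicalEvent(
                event_type="resection",
                t=cut,
                histology=Histology(
                    str(rng.choice(["tumor", "necrosis", "both"]))
                ),
            ),
        )
    return LesionRecord(lesion_id=lesion_id, measurements=measurements, events=events)
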
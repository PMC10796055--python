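"""Synthetic cohorts with the structure of the random-generation studies.

No human recordings ship with this package; instead, cohorts of synthetic
participants are generated from a known ground-truth model so the full
measurement and model-comparison pipeline can be exercised end to end.

The ``heights`` experiment gives every participant two within-participant
conditions — a Gaussian height target (N(176.4, 12) cm) and a Uniform
height target (Beta(1.27, 1.43) scaled to 122-219 cm) — with 150 responses
per 5-minute sequence (pace 30/min), uttered as integer centimetres.  The
``syllables`` experiment gives two production blocks on a learned 7-item
layout (line or hex grid), 355 responses each (the observed ~71/min pace).

Ground truth (model, parameters, seeds, domain specs) is recorded in a
manifest next to the sequences, so recovery analyses can score themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import TargetDistribution, heights_gaussian, heights_uniform, syllables
from .samplers import MODELS, SamplerSpec, draw_params_from_prior, generate_sequence
from .sumstats import Sequence

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_participant",
    "generate_cohort",
    "write_sequences",
    "read_sequences",
    "write_cohort",
    "read_cohort",
    "condition_domains",
]

DEFAULT_LENGTHS = {"heights": 150, "syllables": 355}

CSV_COLUMNS = ["participant", "condition", "trial", "response", "x", "y"]


def condition_domains(experiment: str, layout: str = "line7") -> dict[str, TargetDistribution]:
    """The per-condition target distributions of an experiment."""
    if experiment == "heights":
        return {"gaussian": heights_gaussian(), "uniform": heights_uniform()}
    if experiment == "syllables":
        dom = syllables(layout)
        return {"block1": dom, "block2": dom}
    raise ValueError(f"unknown experiment {experiment!r} (heights | syllables)")


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a synthetic cohort.

    ``model_id`` is the ground-truth generator for every participant;
    ``params`` fixes its parameters, or ``None`` draws them fresh from the
    prior per participant and condition (the widths of the two height
    domains differ, so prior draws are per condition).
    """

    n_participants: int
    experiment: str = "heights"
    model_id: str = "iid"
    params: dict | None = None
    layout: str = "line7"
    lengths: dict[str, int] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.experiment not in DEFAULT_LENGTHS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        for length in (self.lengths or {}).values():
            if length < 50:
                raise ValueError("condition lengths must be >= 50")


@dataclass
class Cohort:
    sequences: list[Sequence]
    manifest: dict
    config: CohortConfig | None = field(default=None, repr=False)


def generate_participant(model_id: str, params: dict | None, experiment: str,
                         lengths: dict[str, int] | None = None, seed=None,
                         layout: str = "line7", participant_id: str = "p0") -> Cohort:
    """Generate one synthetic participant: one sequence per condition, plus
    a manifest entry recording the ground truth."""
    domains = condition_domains(experiment, layout)
    if model_id == "schema" and any(d.ndim == 2 for d in domains.values()):
        raise ValueError("the schema model cannot sample in two-dimensional domains")
    default_len = DEFAULT_LENGTHS[experiment]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cond_seeds = ss.spawn(len(domains))
    sequences = []
    entry = {"id": participant_id, "model": model_id, "conditions": {}}
    for (cond, dom), cseed in zip(domains.items(), cond_seeds):
        seq_seed = int(cseed.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(seq_seed)
        p = params if params is not None else draw_params_from_prior(model_id, dom, rng)
        length = (lengths or {}).get(cond, default_len)
        seq = generate_sequence(SamplerSpec(model_id, p), dom, length=length, rng=rng,
                                meta={"participant": participant_id, "condition": cond})
        sequences.append(seq)
        entry["conditions"][cond] = {
            "domain": json.loads(dom.to_json()),
            "params": _jsonable(p),
            "seed": seq_seed,
            "length": length,
        }
    manifest = {"experiment": experiment, "layout": layout, "participants": [entry]}
    return Cohort(sequences=sequences, manifest=manifest)


def generate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate a full cohort; deterministic per config seed.  If
    ``out_dir`` is given, also write ``sequences.csv`` and
    ``manifest.json`` there."""
    ss = np.random.SeedSequence(config.seed)
    participant_seeds = ss.spawn(config.n_participants)
    sequences: list[Sequence] = []
    participants = []
    for i, pseed in enumerate(participant_seeds):
        part = generate_participant(
            config.model_id, config.params, config.experiment,
            lengths=config.lengths, seed=pseed, layout=config.layout,
            participant_id=f"p{i:03d}",
        )
        sequences.extend(part.sequences)
        participants.extend(part.manifest["participants"])
    manifest = {
        "experiment": config.experiment,
        "layout": config.layout,
        "model": config.model_id,
        "seed": config.seed,
        "participants": participants,
    }
    cohort = Cohort(sequences=sequences, manifest=manifest, config=config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_sequences(sequences: list[Sequence], path) -> None:
    """Write sequences as long-format CSV: participant, condition, trial,
    response, x, y (x and y blank for univariate domains)."""
    rows = []
    for seq in sequences:
        pid = seq.meta.get("participant", "")
        cond = seq.meta.get("condition", "")
        pos = seq.positions if (seq.domain is not None and seq.domain.ndim == 2) else None
        for t, r in enumerate(seq.responses):
            row = {"participant": pid, "condition": cond, "trial": t,
                   "response": r,
                   "x": pos[t, 0] if pos is not None else np.nan,
                   "y": pos[t, 1] if pos is not None else np.nan}
            rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_sequences(path, domains: dict[str, TargetDistribution] | None = None) -> list[Sequence]:
    """Read a sequences CSV back into :class:`Sequence` objects.

    If per-condition ``domains`` are supplied, every response is validated
    against the domain grid (and, for hex layouts, against its x/y
    columns); validation errors cite the offending CSV row.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sequences = []
    for (pid, cond), grp in df.groupby(["participant", "condition"], sort=False):
        grp = grp.sort_values("trial")
        dom = None
        if domains is not None:
            if cond not in domains:
                row = int(grp.index[0]) + 2  # header + 0-base
                raise ValueError(f"{path} row {row}: unknown condition {cond!r}")
            dom = domains[cond]
            _validate_rows(grp, dom, path)
        responses = grp["response"].to_numpy()
        if dom is not None and dom.family != "gaussian":
            responses = responses.astype(int)
        sequences.append(Sequence(responses=responses, domain=dom,
                                  meta={"participant": pid, "condition": cond}))
    return sequences


def _validate_rows(grp: pd.DataFrame, dom: TargetDistribution, path) -> None:
    for idx, rec in grp.iterrows():
        row = int(idx) + 2
        r = rec["response"]
        if dom.family == "gaussian":
            ok = float(r) == round(float(r))
        else:
            ok = int(r) in set(int(v) for v in dom.grid_values)
        if not ok:
            raise ValueError(f"{path} row {row}: response {r!r} is off the "
                             f"{dom.family} domain grid")
        if dom.ndim == 2 and not (pd.isna(rec["x"]) and pd.isna(rec["y"])):
            expect = dom.layout.positions[int(r) - 1]
            if not (np.isclose(rec["x"], expect[0]) and np.isclose(rec["y"], expect[1])):
                raise ValueError(f"{path} row {row}: x/y columns inconsistent "
                                 f"with item {int(r)}")


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sequences(cohort.sequences, out / "sequences.csv")
    (out / "manifest.json").write_text(json.dumps(_jsonable(cohort.manifest), indent=1))


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    domains = {
        cond: TargetDistribution.from_json(json.dumps(spec["domain"]))
        for part in manifest["participants"]
        for cond, spec in part["conditions"].items()
    }
    sequences = read_sequences(src / "sequences.csv", domains=domains)
    return Cohort(sequences=sequences, manifest=manifest)
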
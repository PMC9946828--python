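"""Structured YAML config for runs, bin specs and toy-family specs."""

from __future__ import annotations

import yaml

from .fixtures import ToyFamilySpec
from .geometry import BinSpec
from .losses import LossConfig
from .mcmc import AnnealSchedule

__all__ = [
    "load_yaml",
    "dump_yaml",
    "loss_config_from_dict",
    "schedule_from_dict",
    "binspec_from_file",
    "binspec_to_file",
    "toy_spec_from_dict",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return doc or {}


def dump_yaml(doc: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def loss_config_from_dict(d: dict | None) -> LossConfig:
    d = d or {}
    return LossConfig(
        w_restraint=float(d.get("w_restraint", 1.0)),
        w_confidence=float(d.get("w_confidence", 1.0)),
        channel_weights=dict(
            d.get("channel_weights",
                  {"d": 1.0, "omega": 1.0, "theta": 1.0, "phi": 1.0})
        ),
        kl_floor=float(d.get("kl_floor", 1e-8)),
    )


def schedule_from_dict(d: dict | None) -> AnnealSchedule:
    d = d or {}
    return AnnealSchedule(
        T_initial=float(d.get("T_initial", 0.02)),
        T_final=float(d.get("T_final", 0.0002)),
        n_steps=int(d.get("n_steps", 2000)),
        mode=str(d.get("mode", "geometric")),
    )


def binspec_from_file(path) -> BinSpec:
    return BinSpec.from_dict(load_yaml(path))


def binspec_to_file(spec: BinSpec, path) -> None:
    dump_yaml(spec.to_dict(), path)


def toy_spec_from_dict(d: dict) -> ToyFamilySpec:
    plan = []
    for entry in d.get("segment_plan", []):
        kind, length = entry[0], entry[1]
        plan.append((kind, tuple(length) if kind == "loop" else int(length)))
    kwargs = dict(
        n_members=int(d.get("n_members", 6)),
        segment_plan=tuple(plan) or ToyFamilySpec().segment_plan,
        coordinate_jitter=float(d.get("coordinate_jitter", 0.05)),
        loop_length_seed=int(d.get("loop_length_seed", 0)),
        jitter_seed=int(d.get("jitter_seed", 0)),
        planted_sequence=d.get("planted_sequence"),
        kappa=float(d.get("kappa", 3.0)),
    )
    if "alphabet" in d:
        kwargs["alphabet"] = str(d["alphabet"])
    return ToyFamilySpec(**kwargs)
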
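"""YAML/JSON configuration for the plant and task definitions.

A config file holds a ``model:`` section with plant parameters and a
``tasks:`` section whose entries override or extend the built-in task
definitions.  Every printed constant is overridable::

    model:
      m: 1.0
      b: 0.1
      tau: 0.06
      dt: 0.01
    tasks:
      stop:
        duration: 0.700
      slow_stop:
        base: stop
        duration: 0.900
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .lqr import StateSpaceModel, build_point_mass_model
from .tasks import TaskSpec, make_task

__all__ = ["load_config", "model_from_dict", "tasks_from_dict"]

_MODEL_KEYS = {"m", "b", "tau", "dt", "n_dims"}
_TASK_KEYS = {
    "target_distance",
    "duration",
    "w_p",
    "w_v",
    "w_f",
    "activation_cost",
    "activation_params",
    "measurement_distance",
}


def model_from_dict(section: dict | None) -> StateSpaceModel:
    section = dict(section or {})
    unknown = set(section) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    return build_point_mass_model(**section)


def tasks_from_dict(section: dict | None) -> dict[str, TaskSpec]:
    """Built-in tasks plus any overrides/additions from the config."""
    tasks = {name: make_task(name) for name in ("stop", "hit", "long_stop")}
    for name, fields in (section or {}).items():
        fields = dict(fields or {})
        base = fields.pop("base", name if name in tasks else "stop")
        unknown = set(fields) - _TASK_KEYS
        if unknown:
            raise ValueError(f"unknown task parameters for {name!r}: {sorted(unknown)}")
        if "activation_params" in fields and fields["activation_params"] is not None:
            fields["activation_params"] = tuple(float(v) for v in fields["activation_params"])
        tasks[name] = replace(make_task(base) if base in ("stop", "hit", "long_stop") else tasks[base],
                              name=name, **fields)
    return tasks


def load_config(path: str | Path) -> tuple[StateSpaceModel, dict[str, TaskSpec]]:
    """Read a YAML (or JSON; YAML is a superset) config file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return model_from_dict(data.get("model")), tasks_from_dict(data.get("tasks"))
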
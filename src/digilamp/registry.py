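"""Bundled registry of genome, seed-tissue and GM-event specifications.

Ships the maize genome (2.4 Gbp / 2.6 pg haploid), the diploid-embryo +
triploid-endosperm seed tissue model, and the Bt11, NK603 and Mon810 events
with their per-locus target multiplicities. User config files use the same
YAML shape and are loaded with the same functions.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Union

import yaml

from .copy_accounting import GenomeSpec, SampleSpec, SeedTissueModel, TransgeneEventSpec
from .exceptions import ConfigError


def _bundled_registry_text() -> str:
    return (
        importlib.resources.files("digilamp")
        .joinpath("data/events.yaml")
        .read_text(encoding="utf-8")
    )


def load_registry(path: Union[str, Path, None] = None) -> dict[str, Any]:
    """Parse a registry/config file into spec objects.

    Returns a dict with keys ``genome`` (GenomeSpec), ``seed_tissue``
    (SeedTissueModel), ``events`` (name -> TransgeneEventSpec) and, when
    present, ``sample`` (SampleSpec). With no path, loads the bundled
    maize/Bt11/NK603/Mon810 registry.
    """
    if path is None:
        raw = yaml.safe_load(_bundled_registry_text())
    else:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("registry file must contain a mapping at top level")
    out: dict[str, Any] = {}
    try:
        if "genome" in raw:
            out["genome"] = GenomeSpec(**raw["genome"])
        if "seed_tissue" in raw:
            out["seed_tissue"] = SeedTissueModel(**raw["seed_tissue"])
        if "events" in raw:
            out["events"] = {
                name: TransgeneEventSpec(**spec) for name, spec in raw["events"].items()
            }
        if "sample" in raw:
            out["sample"] = SampleSpec(**raw["sample"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid registry entry: {exc}") from exc
    return out


def default_genome() -> GenomeSpec:
    return load_registry()["genome"]


def default_seed_tissue() -> SeedTissueModel:
    return load_registry()["seed_tissue"]


def get_event(name: str) -> TransgeneEventSpec:
    events = load_registry()["events"]
    if name not in events:
        raise ConfigError(f"unknown event {name!r}; bundled: {sorted(events)}")
    return events[name]
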
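"""Structured run configuration (YAML dialect) for the screening funnel.

One config file drives the whole pipeline; every value has an explicit
default traceable to the method (2 uM activity threshold, QED > 0.85,
similarity cutoff at the 80th percentile / > 0.83, 100-member ensemble
of 700-tree forests on 90% bags).  Unknown keys are rejected with an
error naming every offence, and a loaded config round-trips through
``save``/``load_config`` unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from plifscreen.simulate import GeneratorConfig


@dataclass
class CurationSection:
    activity_threshold_um: float = 2.0
    qed_min: float = 0.85
    pains: bool = True
    apply_prefilter: bool = False   # drug-likeness gate, for real libraries


@dataclass
class PlifSection:
    top_n: int = 5
    min_poses: int = 4
    similarity_percentile: float = 80.0
    sim_cutoff: float | None = None   # None -> derive from the percentile
    reference_fingerprint: str | None = None  # None -> packaged reference


@dataclass
class MiningSection:
    min_size: int = 2
    max_size: int = 6
    min_coverage: float = 0.5


@dataclass
class QsarSection:
    test_fraction: float = 0.3
    cv_folds: int = 10
    n_members: int = 100
    n_trees: int = 700
    bag_fraction: float = 0.9
    optimize: bool = False            # run the full 70-config grid search
    trees_grid: list = field(default_factory=lambda: list(range(100, 1001, 100)))
    blocks: list = field(default_factory=lambda: ["physchem", "residue_contacts"])
    rdn_bandwidth: float = 0.25
    ad_coverage: float = 0.3          # accept the top fraction by reliability


@dataclass
class ScreenSection:
    k: int = 50
    min_mcs_atoms: int = 3
    mcs_timeout: int = 5
    n_mcs_refs: int = 50              # cap on MCS reference compounds


@dataclass
class RunConfig:
    """Full pipeline configuration; serializable and hashable."""

    seed: int = 0
    output_dir: str = "runs/plifscreen"
    simulate: GeneratorConfig = field(default_factory=GeneratorConfig)
    curation: CurationSection = field(default_factory=CurationSection)
    plif: PlifSection = field(default_factory=PlifSection)
    mining: MiningSection = field(default_factory=MiningSection)
    qsar: QsarSection = field(default_factory=QsarSection)
    screen: ScreenSection = field(default_factory=ScreenSection)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: convert(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return convert(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_SECTIONS = {
    "simulate": GeneratorConfig,
    "curation": CurationSection,
    "plif": PlifSection,
    "mining": MiningSection,
    "qsar": QsarSection,
    "screen": ScreenSection,
}


def _build_section(cls, data: dict, prefix: str, errors: list):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            errors.append(f"unknown key: {prefix}{key}")
            continue
        if isinstance(value, list):
            value = tuple(value) if cls is GeneratorConfig else value
        kwargs[key] = value
    if errors:
        return None
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"invalid {prefix.rstrip('.') or 'top-level'} section: {exc}")
        return None


def config_from_dict(data: dict) -> RunConfig:
    """Validate a nested dict into a :class:`RunConfig`.

    Raises ``ValueError`` listing *every* unknown key and invalid value.
    """
    errors: list[str] = []
    top_valid = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top_valid:
            errors.append(f"unknown key: {key}")
            continue
        if key in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(f"section {key} must be a mapping")
                continue
            section = _build_section(_SECTIONS[key], value, f"{key}.", errors)
            if section is not None:
                kwargs[key] = section
        else:
            kwargs[key] = value
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)
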
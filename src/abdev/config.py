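"""Packaged configuration: per-residue scales, CDR rules, platform defaults."""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources

import yaml

#: The 12 biophysical assay platforms modelled by the package.
PLATFORMS = (
    "HIC", "SMAC", "CIC", "ACSINS", "ELISA", "BVP",
    "SGAC-SINS", "PSR", "HEK", "DSF", "CSI", "ACC-STAB",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _load_yaml(name: str) -> dict:
    text = resources.files("abdev.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=None)
def _scales() -> dict:
    return _load_yaml("scales.yaml")


@lru_cache(maxsize=None)
def _cdr_rules() -> dict:
    return _load_yaml("cdr_rules.yaml")


@lru_cache(maxsize=None)
def _platform_defaults() -> dict:
    return _load_yaml("platforms.yaml")


def load_scales() -> dict:
    """Per-residue scale tables (mem, fld, dis, bet) and the pKa table."""
    return copy.deepcopy(_scales())


def load_cdr_rules() -> dict:
    """Anchor-rule constants for CDR identification."""
    return copy.deepcopy(_cdr_rules())


def load_platform_defaults() -> dict:
    """Default platform configs, learner grids, meta groups, VIF threshold."""
    return copy.deepcopy(_platform_defaults())


def canonical_platform(name: str) -> str | None:
    """Map a column name to its canonical platform id (case-insensitive,

    tolerant of ``_``/``-`` differences); None if unrecognized.
    """
    key = name.strip().upper().replace("_", "-")
    for pid in PLATFORMS:
        if key == pid or key.replace("-", "") == pid.replace("-", ""):
            return pid
    return None
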
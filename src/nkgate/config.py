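"""Structured-text (YAML) configuration for cohort generation.

Example::

    condition: HIV_untreated
    n_donors: 12
    n_events: 30000
    seed: 7
    abundance_jitter: 20000
    abundance_overrides:
      pDC: 0.012
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigurationError
from .populations import CohortConfig

_KNOWN_KEYS = {"condition", "n_donors", "n_events", "seed",
               "abundance_jitter", "abundance_overrides"}


def cohort_config_from_dict(doc: dict) -> CohortConfig:
    if not isinstance(doc, dict):
        raise ConfigurationError("cohort config must be a mapping")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
    overrides = doc.get("abundance_overrides") or {}
    if not isinstance(overrides, dict):
        raise ConfigurationError("abundance_overrides must be a mapping")
    jitter = doc.get("abundance_jitter", 20_000.0)
    jitter = None if jitter in (None, "none") else float(jitter)
    return CohortConfig(
        condition=doc.get("condition", "HD"),
        n_donors=int(doc.get("n_donors", 20)),
        n_events=int(doc.get("n_events", 50_000)),
        seed=int(doc.get("seed", 42)),
        abundance_jitter=jitter,
        abundance_overrides={str(k): float(v) for k, v in overrides.items()},
    )


def load_cohort_config(path) -> CohortConfig:
    return cohort_config_from_dict(yaml.safe_load(Path(path).read_text()))
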
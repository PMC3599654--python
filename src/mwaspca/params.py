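"""Run-controlling parameter file: ``key = value`` lines, ``#`` comments.

One file selects which procedures run (any subset of ``simulate``, ``blocks``,
``pca``, ``assoc``) and carries their settings, so a whole pipeline is
reproducible from a single text artifact.  Unknown keys are an error rather
than a warning: a typo in a threshold name must not silently fall back to a
default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Callable

PROCEDURES = ("simulate", "blocks", "pca", "assoc")


def _parse_bool(s: str) -> bool:
    if s.lower() in ("true", "yes", "1"):
        return True
    if s.lower() in ("false", "no", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_threshold(s: str) -> float:
    v = float(s)
    if not -1.0 <= v <= 1.0:
        raise ValueError(f"threshold outside [-1, 1]: {v}")
    return v


def _parse_pos_int(s: str) -> int:
    v = int(s)
    if v < 1:
        raise ValueError(f"must be a positive integer: {v}")
    return v


def _parse_nonneg_int(s: str) -> int:
    v = int(s)
    if v < 0:
        raise ValueError(f"must be non-negative: {v}")
    return v


def _parse_list(s: str) -> tuple[str, ...]:
    return tuple(x.strip() for x in s.split(",") if x.strip())


def _parse_choice(*choices: str) -> Callable[[str], str]:
    def parse(s: str) -> str:
        if s not in choices:
            raise ValueError(f"expected one of {choices}, got {s!r}")
        return s

    return parse


# key -> (parser, default); None default means "unset"
_SCHEMA: dict[str, tuple[Callable[[str], Any], Any]] = {
    "procedures": (_parse_list, ()),
    # paths
    "matrix": (str, None),
    "include_sites": (str, None),
    "exclude_sites": (str, None),
    "covariates": (str, None),
    "phenotype": (str, None),
    "pheno_column": (str, None),
    "pcs": (str, None),
    "out_prefix": (str, None),
    # block creation (two cascaded stages; stage-2 thresholds follow the
    # looser "biological correlation" stage)
    "t1": (_parse_threshold, 0.9),
    "t2": (_parse_threshold, 0.9),
    "nt": (_parse_pos_int, 2),
    "two_stage": (_parse_bool, True),
    "stage2_t1": (_parse_threshold, 0.6),
    "stage2_t2": (_parse_threshold, 0.6),
    "stage2_nt": (_parse_pos_int, 2),
    # PCA
    "pca_mode": (_parse_choice("covariance", "correlation"), "covariance"),
    "chunk_size": (_parse_pos_int, 350),
    "n_pcs": (_parse_pos_int, 10),
    "n_loadings": (_parse_nonneg_int, 0),
    "regress_out": (_parse_list, ()),
    # association
    "assoc_covariates": (_parse_list, ()),
    "assoc_n_pcs": (_parse_nonneg_int, 0),
    # execution
    "execution_mode": (_parse_choice("sequential", "batch-files"), "sequential"),
    "seed": (int, 0),
    # simulator
    "sim_preset": (str, None),
    "sim_sites_per_chrom_mean": (lambda s: float(s), 4000.0),
}

# keys that must be present (no usable default) when a procedure is selected
_MANDATORY: dict[str, tuple[str, ...]] = {
    "simulate": ("sim_preset",),
    "blocks": (),
    "pca": (),
    "assoc": ("phenotype",),
}


@dataclass
class ParameterFile:
    """Validated key -> typed-value mapping for one run."""

    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.values.get(key, default)

    @property
    def procedures(self) -> tuple[str, ...]:
        return self.values["procedures"]


def parse_parameter_file(path: str | os.PathLike) -> ParameterFile:
    """Parse and validate; deterministic mapping with defaults applied."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _SCHEMA:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            if key in raw:
                raise ValueError(f"{path}:{ln}: duplicate key {key!r}")
            raw[key] = value

    values: dict[str, Any] = {}
    for key, (parser, default) in _SCHEMA.items():
        if key in raw:
            try:
                values[key] = parser(raw[key])
            except ValueError as exc:
                raise ValueError(f"{path}: key {key!r}: {exc}") from None
        else:
            values[key] = default

    procedures = values["procedures"]
    if not procedures:
        raise ValueError(f"{path}: no procedure selected")
    for proc in procedures:
        if proc not in PROCEDURES:
            raise ValueError(f"{path}: unknown procedure {proc!r}")
    if values["out_prefix"] is None:
        raise ValueError(f"{path}: out_prefix is mandatory")
    for proc in procedures:
        for key in _MANDATORY[proc]:
            if key == "phenotype" and "simulate" in procedures:
                continue  # the simulator writes the phenotype table
            if values[key] is None:
                raise ValueError(f"{path}: procedure {proc!r} requires key {key!r}")
    # whether `matrix` may be omitted depends on upstream stages producing it;
    # that dependency resolution is the pipeline planner's job, not a parse error
    return ParameterFile(values)
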
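"""Model parameters for the ChIP-seq generative model.

The simulator is governed by a small set of experiment-level parameters:
a gamma fragment-length distribution (shape ``k``, scale ``theta``, mean
``k * theta`` bp), the pulldown pair ``(f, s)`` — the fraction of the
genome bound by the factor and the fraction of pulled-down reads that
originate from true binding sites (the SPOT/FRIP score) — the PCR
parameter ``p`` (probability a fragment has no duplicates), and per-base
sequencing error rates.  The antibody enrichment ratio ``alpha`` (the
relative probability of pulling down a bound versus an unbound fragment)
is always derived on demand from ``(f, s)`` and never stored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "ChipModel",
    "ExperimentParams",
    "ModelValidationError",
    "compute_alpha",
    "read_model",
    "write_model",
]

PathLike = Union[str, Path]


class ModelValidationError(ValueError):
    """A model field is missing or outside its valid range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def compute_alpha(f: float, s: float) -> float:
    """Enrichment ratio alpha = s(1-f) / ((1-s) f).

    ``alpha`` is the ratio of the probability of pulling down a bound
    versus an unbound fragment.  It is strictly increasing in ``s``
    (a cleaner pulldown implies stronger enrichment) and strictly
    decreasing in ``f`` (a factor covering more of the genome needs less
    enrichment to reach the same signal fraction).

    Raises
    ------
    ModelValidationError
        If ``f`` or ``s`` lies outside the open interval (0, 1); at the
        boundary the experiment is degenerate (nothing or everything is
        bound) and the ratio is undefined.
    """
    if not (0.0 < f < 1.0):
        raise ModelValidationError("f", f"must be in (0, 1), got {f!r}")
    if not (0.0 < s < 1.0):
        raise ModelValidationError("s", f"must be in (0, 1), got {s!r}")
    return s * (1.0 - f) / ((1.0 - s) * f)


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ModelValidationError(field, msg)


@dataclass(frozen=True)
class ChipModel:
    """Complete parameter set of the generative ChIP-seq model."""

    frag_shape: float
    frag_scale: float
    f: float
    s: float
    pcr_p: float
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frag_shape", "frag_scale"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, name, f"must be > 0, got {v!r}")
        for name in ("f", "s"):
            v = getattr(self, name)
            _require(0.0 < v < 1.0, name, f"must be in (0, 1), got {v!r}")
        _require(0.0 < self.pcr_p <= 1.0, "pcr_p", f"must be in (0, 1], got {self.pcr_p!r}")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            _require(0.0 <= v < 1.0, name, f"must be in [0, 1), got {v!r}")
        total = self.sub_rate + self.ins_rate + self.del_rate
        _require(total < 1.0, "sub_rate", f"error rates must sum to < 1, got {total!r}")

    @property
    def frag_mean(self) -> float:
        """Mean fragment length in bp (shape * scale)."""
        return self.frag_shape * self.frag_scale

    @property
    def alpha(self) -> float:
        """Pulldown enrichment ratio derived from (f, s)."""
        return compute_alpha(self.f, self.s)

    def replace(self, **changes) -> "ChipModel":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ExperimentParams:
    """Experimental settings: read count, read length, layout, rounds, seed.

    ``numreads`` counts reads for single-end runs and read *pairs* for
    paired-end runs.  ``numcopies`` is the number of simulation rounds,
    i.e. how many times the reference genome is sheared; it is related
    to, but not directly comparable with, the number of input cells.
    """

    numreads: int
    readlen: int
    paired: bool = False
    numcopies: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.numreads >= 1, "numreads", f"must be >= 1, got {self.numreads!r}")
        _require(self.readlen >= 1, "readlen", f"must be >= 1, got {self.readlen!r}")
        _require(self.numcopies >= 1, "numcopies", f"must be >= 1, got {self.numcopies!r}")


# JSON model-file schema.  Nested sections keep related parameters
# together and make shape/rate confusion impossible: the "frag" section
# records its own parameterization.
_FRAG_NOTE = "gamma(shape, scale); mean fragment length = shape*scale bp"

_SCHEMA = {
    "frag": {"shape", "scale", "parameterization"},
    "pulldown": {"f", "s"},
    "pcr": {"p"},
    "seq_error": {"sub", "ins", "del"},
}


def write_model(model: ChipModel, path: PathLike) -> None:
    """Serialize a model to JSON (full float precision, round-trip safe)."""
    doc = {
        "frag": {
            "shape": model.frag_shape,
            "scale": model.frag_scale,
            "parameterization": _FRAG_NOTE,
        },
        "pulldown": {"f": model.f, "s": model.s},
        "pcr": {"p": model.pcr_p},
        "seq_error": {
            "sub": model.sub_rate,
            "ins": model.ins_rate,
            "del": model.del_rate,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _get(doc: dict, section: str, key: str, default=None):
    sec = doc.get(section)
    if sec is None:
        raise ModelValidationError(section, "missing section in model file")
    if key not in sec:
        if default is not None:
            return default
        name = f"{section}.{key}" if section != "frag" else f"frag_{key}"
        raise ModelValidationError(name, "missing field in model file")
    val = sec[key]
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise ModelValidationError(f"{section}.{key}", f"must be numeric, got {val!r}")
    return float(val)


def read_model(path: PathLike) -> ChipModel:
    """Read and validate a model JSON file.

    Unknown sections or keys are rejected so that typos (e.g. "rate"
    instead of "scale") fail loudly instead of silently falling back to
    defaults.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ModelValidationError("model", "model file must contain a JSON object")
    for section, content in doc.items():
        if section not in _SCHEMA:
            raise ModelValidationError(section, "unknown section in model file")
        if not isinstance(content, dict):
            raise ModelValidationError(section, "section must be a JSON object")
        for key in content:
            if key not in _SCHEMA[section]:
                raise ModelValidationError(f"{section}.{key}", "unknown key in model file")
    frag_shape = _get(doc, "frag", "shape")
    frag_scale = _get(doc, "frag", "scale")
    f = _get(doc, "pulldown", "f")
    s = _get(doc, "pulldown", "s")
    p = _get(doc, "pcr", "p")
    err = doc.get("seq_error", {})
    return ChipModel(
        frag_shape=frag_shape,
        frag_scale=frag_scale,
        f=f,
        s=s,
        pcr_p=p,
        sub_rate=float(err.get("sub", 0.0)),
        ins_rate=float(err.get("ins", 0.0)),
        del_rate=float(err.get("del", 0.0)),
    )
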
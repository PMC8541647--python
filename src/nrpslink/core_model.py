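"""Shared domain types for monomer-sequence matching.

The aligned units on both sides of a BGC-NRP comparison are *monomers*:
a core residue name drawn from a configurable alphabet of supported
residues, a methylation flag and a D/L stereochemistry flag.  BGC-side
monomers additionally carry an integer specificity score in [0..100]
summarising how confident the adenylation-domain substrate prediction is;
the score is discretized into a small number of levels before it enters
the scoring model.

Flags are encoded as "trits": -1 / +1 for the two defined states and 0
for "undetermined / irrelevant" (achiral residues, or the undefined BGC
monomer used by the null model).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ResidueAlphabet",
    "NRPMonomer",
    "BGCMonomer",
    "Gap",
    "NRP_GAP",
    "BGC_GAP",
    "ScoringParams",
    "load_alphabet",
    "default_alphabet",
    "discretize_specificity",
    "validate_params",
    "load_params",
    "save_params",
    "default_params",
]

#: Reserved symbol for any residue outside the supported alphabet.  Two
#: unsupported residues are never considered equal to each other.
UNSUPPORTED_SIGN = "*"

#: Default cut points (inclusive upper edges) discretizing the raw
#: specificity scale [1..100] into five levels; score 0 is the reserved
#: "unreliable prediction" level 0.
DEFAULT_LEVEL_BOUNDARIES = (60, 70, 80, 90, 100)


class AlphabetError(ValueError):
    """Malformed or inconsistent residue-alphabet input."""


@dataclass(frozen=True)
class ResidueAlphabet:
    """The ordered set of supported core residues plus the reserved
    unsupported-residue sign."""

    residues: tuple[str, ...]
    unsupported_sign: str = UNSUPPORTED_SIGN

    def __post_init__(self) -> None:
        seen = set()
        for name in self.residues:
            if not name:
                raise AlphabetError("empty residue name")
            if name != name.strip().lower():
                raise AlphabetError(f"residue name not normalized: {name!r}")
            if name in seen:
                raise AlphabetError(f"duplicate residue: {name!r}")
            seen.add(name)
        if self.unsupported_sign in seen:
            raise AlphabetError("unsupported_sign collides with a residue name")

    def __contains__(self, residue: str) -> bool:
        return residue in set(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def extended(self) -> tuple[str, ...]:
        """Supported residues plus the unsupported sign."""
        return self.residues + (self.unsupported_sign,)

    def normalize(self, residue: str) -> str:
        """Map an arbitrary residue name into the extended alphabet."""
        name = residue.strip().lower()
        return name if name in self else self.unsupported_sign


def load_alphabet(path: str | Path, unsupported_sign: str = UNSUPPORTED_SIGN) -> ResidueAlphabet:
    """Read a residue alphabet from a two-column TSV (name, optional frequency).

    Blank lines and lines starting with ``#`` are ignored.  Raises
    :class:`AlphabetError` naming the offending line on malformed rows and
    on duplicate residues.
    """
    residues: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) > 2:
                raise AlphabetError(f"{path}:{lineno}: expected 1-2 columns, got {len(fields)}")
            name = fields[0].strip().lower()
            if not name:
                raise AlphabetError(f"{path}:{lineno}: empty residue name")
            if len(fields) == 2 and fields[1].strip():
                try:
                    float(fields[1])
                except ValueError as exc:
                    raise AlphabetError(f"{path}:{lineno}: bad frequency {fields[1]!r}") from exc
            if name in residues:
                raise AlphabetError(f"{path}:{lineno}: duplicate residue {name!r}")
            residues.append(name)
    return ResidueAlphabet(tuple(residues), unsupported_sign)


def default_alphabet() -> ResidueAlphabet:
    """The alphabet shipped with the package (58 residues: the 20
    proteinogenic amino acids plus common nonribosomal monomers)."""
    with resources.as_file(resources.files("nrpslink") / "data" / "alphabet.tsv") as p:
        return load_alphabet(p)


@dataclass(frozen=True)
class NRPMonomer:
    """A monomer obtained from a peptide structure: core residue (possibly
    the unsupported sign), methylation and stereo flags.  ``stereo = 0``
    marks achiral or undetermined stereochemistry and is allowed only on
    this (structure) side."""

    residue: str
    methylated: int = -1
    stereo: int = 0

    def __post_init__(self) -> None:
        if self.methylated not in (-1, 1):
            raise ValueError(f"methylated must be -1/+1, got {self.methylated}")
        if self.stereo not in (-1, 0, 1):
            raise ValueError(f"stereo must be -1/0/+1, got {self.stereo}")


@dataclass(frozen=True)
class BGCMonomer:
    """A monomer predicted from an NRPS module: specificity score,
    predicted residue, methylation and stereo flags.

    The *undefined* monomer (specificity 0, unsupported residue, both
    flags 0) models a module about which nothing is known; it is the unit
    of the null hypothesis sequence.
    """

    specificity: int
    residue: str
    methylated: int
    stereo: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.specificity <= 100:
            raise ValueError(f"specificity out of [0..100]: {self.specificity}")
        if self.undefined:
            if self.specificity != 0 or self.methylated != 0 or self.stereo != 0:
                raise ValueError("undefined BGC monomer must be (0, sign, 0, 0)")
        else:
            if self.methylated not in (-1, 1) or self.stereo not in (-1, 1):
                raise ValueError("defined BGC monomer flags must be -1/+1")


def undefined_bgc_monomer(alphabet: ResidueAlphabet) -> BGCMonomer:
    """The undefined BGC monomer for the given alphabet's unsupported sign."""
    return BGCMonomer(0, alphabet.unsupported_sign, 0, 0, undefined=True)


@dataclass(frozen=True)
class Gap:
    """Absence of a monomer on one side of an alignment column; a gap
    never aligns against another gap."""

    side: str  # "nrp" or "bgc"

    def __post_init__(self) -> None:
        if self.side not in ("nrp", "bgc"):
            raise ValueError(f"gap side must be 'nrp' or 'bgc', got {self.side!r}")


NRP_GAP = Gap("nrp")
BGC_GAP = Gap("bgc")


@dataclass
class ScoringParams:
    """All probabilities of the log-odds scoring model.

    * ``p_match_a[level]`` — probability that the structure residue equals
      the predicted residue given the prediction's discretized specificity
      level (level 0 is the reserved "unreliable" level, fixed at 0).
    * ``p_a`` — background frequency of each residue of the extended
      alphabet (supported residues + unsupported sign) among NRP monomers.
    * ``p_m`` / ``p_e`` — background frequencies of the methylation /
      stereo states (-1, +1).
    * ``p_match_m`` / ``p_mismatch_m`` — probability of an aligned column
      in which the structure-side methylation flag ``m`` agrees /
      disagrees with the gene-side flag, keyed by the structure-side
      value ``m``; ``p_match_e`` / ``p_mismatch_e`` likewise for stereo.
    * ``p_insertion`` / ``p_deletion`` — per-column indel probabilities.
    * ``level_boundaries`` — ascending inclusive upper edges partitioning
      the specificity scale [1..100] into exactly five levels.
    """

    p_match_a: tuple[float, ...]
    p_a: dict[str, float]
    p_m: dict[int, float]
    p_e: dict[int, float]
    p_match_m: dict[int, float]
    p_mismatch_m: dict[int, float]
    p_match_e: dict[int, float]
    p_mismatch_e: dict[int, float]
    p_insertion: float
    p_deletion: float
    level_boundaries: tuple[int, ...] = DEFAULT_LEVEL_BOUNDARIES

    def copy(self) -> "ScoringParams":
        return ScoringParams(
            p_match_a=tuple(self.p_match_a),
            p_a=dict(self.p_a),
            p_m=dict(self.p_m),
            p_e=dict(self.p_e),
            p_match_m=dict(self.p_match_m),
            p_mismatch_m=dict(self.p_mismatch_m),
            p_match_e=dict(self.p_match_e),
            p_mismatch_e=dict(self.p_mismatch_e),
            p_insertion=self.p_insertion,
            p_deletion=self.p_deletion,
            level_boundaries=tuple(self.level_boundaries),
        )


def discretize_specificity(s: int, boundaries: Iterable[int] = DEFAULT_LEVEL_BOUNDARIES) -> int:
    """Map a raw specificity score to its discrete level.

    Score 0 (a completely unreliable prediction) maps to the reserved
    level 0; scores in [1..100] map monotonically onto levels 1..5 using
    the inclusive upper edges in ``boundaries``.
    """
    boundaries = tuple(boundaries)
    if not 0 <= s <= 100:
        raise ValueError(f"specificity score out of [0..100]: {s}")
    if boundaries != tuple(sorted(set(boundaries))) or boundaries[-1] != 100:
        raise ValueError(f"invalid level boundaries: {boundaries}")
    if s == 0:
        return 0
    return bisect_left(boundaries, s) + 1


_PROB_TOL = 1e-9  # absolute tolerance of normalization checks


def validate_params(params: ScoringParams) -> list[str]:
    """Check every invariant of :class:`ScoringParams`; return the list of
    violations (empty means valid)."""
    errors: list[str] = []

    def check_prob(name: str, value: float) -> None:
        if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
            errors.append(f"{name}: probability out of range ({value!r})")

    if len(params.p_match_a) != 6:
        errors.append(f"p_match_a must have 6 levels (0..5), got {len(params.p_match_a)}")
    else:
        if params.p_match_a[0] != 0.0:
            errors.append("p_match_a at level 0 must be 0 (unreliable prediction)")
        for lvl, p in enumerate(params.p_match_a):
            check_prob(f"p_match_a[{lvl}]", p)

    for a, p in params.p_a.items():
        check_prob(f"p_a[{a!r}]", p)
    if abs(sum(params.p_a.values()) - 1.0) > _PROB_TOL:
        errors.append(f"p_a must sum to 1, sums to {sum(params.p_a.values()):.12g}")

    for name, table in (("p_m", params.p_m), ("p_e", params.p_e)):
        if set(table) != {-1, 1}:
            errors.append(f"{name} must be keyed by -1/+1")
            continue
        for k, p in table.items():
            check_prob(f"{name}[{k:+d}]", p)
        if abs(table[-1] + table[1] - 1.0) > _PROB_TOL:
            errors.append(f"{name} must sum to 1")

    for name, table in (
        ("p_match_m", params.p_match_m),
        ("p_mismatch_m", params.p_mismatch_m),
        ("p_match_e", params.p_match_e),
        ("p_mismatch_e", params.p_mismatch_e),
    ):
        if set(table) != {-1, 1}:
            errors.append(f"{name} must be keyed by -1/+1")
            continue
        for k, p in table.items():
            check_prob(f"{name}[{k:+d}]", p)

    check_prob("p_insertion", params.p_insertion)
    check_prob("p_deletion", params.p_deletion)

    b = tuple(params.level_boundaries)
    if len(b) != 5 or b != tuple(sorted(set(b))) or b[-1] != 100 or b[0] < 1:
        errors.append(f"level_boundaries must be 5 ascending edges ending at 100, got {b}")

    return errors


# ---------------------------------------------------------------------------
# Parameter file I/O (flat YAML; probabilities written with full precision so
# the file round-trips bit-identically).

def _params_to_dict(params: ScoringParams) -> dict:
    return {
        "p_match_a": [float(p) for p in params.p_match_a],
        "p_a": {a: float(p) for a, p in params.p_a.items()},
        "p_m": {int(k): float(v) for k, v in params.p_m.items()},
        "p_e": {int(k): float(v) for k, v in params.p_e.items()},
        "p_match_m": {int(k): float(v) for k, v in params.p_match_m.items()},
        "p_mismatch_m": {int(k): float(v) for k, v in params.p_mismatch_m.items()},
        "p_match_e": {int(k): float(v) for k, v in params.p_match_e.items()},
        "p_mismatch_e": {int(k): float(v) for k, v in params.p_mismatch_e.items()},
        "p_insertion": float(params.p_insertion),
        "p_deletion": float(params.p_deletion),
        "level_boundaries": [int(b) for b in params.level_boundaries],
    }


def save_params(params: ScoringParams, path: str | Path) -> None:
    """Write a scoring-parameter file (YAML; floats at full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=True, default_flow_style=False)


def load_params(path: str | Path) -> ScoringParams:
    """Read a scoring-parameter file written by :func:`save_params`."""
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    try:
        return ScoringParams(
            p_match_a=tuple(float(p) for p in d["p_match_a"]),
            p_a={str(a): float(p) for a, p in d["p_a"].items()},
            p_m={int(k): float(v) for k, v in d["p_m"].items()},
            p_e={int(k): float(v) for k, v in d["p_e"].items()},
            p_match_m={int(k): float(v) for k, v in d["p_match_m"].items()},
            p_mismatch_m={int(k): float(v) for k, v in d["p_mismatch_m"].items()},
            p_match_e={int(k): float(v) for k, v in d["p_match_e"].items()},
            p_mismatch_e={int(k): float(v) for k, v in d["p_mismatch_e"].items()},
            p_insertion=float(d["p_insertion"]),
            p_deletion=float(d["p_deletion"]),
            level_boundaries=tuple(int(b) for b in d["level_boundaries"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed parameter file {path}: {exc}") from exc


def default_params() -> ScoringParams:
    """The scoring parameters shipped with the package (placeholder values
    intended to be re-learned with the training module)."""
    with resources.as_file(resources.files("nrpslink") / "data" / "params.yaml") as p:
        return load_params(p)
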
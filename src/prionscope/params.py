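"""Scoring parameters for the prion-like composition model.

The scorer is entirely table-driven: a prion-state amino-acid frequency
table ``f_P``, a background table ``f_B``, a log base, a minimum core
length ``c`` (residues), and the two-state transition parameters
(expected prion-run and background-run lengths).  The shipped default
lives in ``data/default_params.tsv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity / non-standard codes scored neutrally (LLR contribution 0)
AMBIGUOUS = "XBZU"

_FREQ_FLOOR = 1e-6


def _normalise(freqs: dict[str, float]) -> dict[str, float]:
    """Apply the pseudocount floor and renormalise to sum exactly 1."""
    floored = {aa: max(float(freqs.get(aa, 0.0)), _FREQ_FLOOR) for aa in AA20}
    total = sum(floored.values())
    if not math.isfinite(total) or total <= 0:
        raise ValueError("frequency table does not sum to a positive finite value")
    return {aa: v / total for aa, v in floored.items()}


@dataclass(frozen=True)
class TransitionParams:
    """Geometric run-length priors for the two-state parse.

    ``prion_run`` / ``background_run`` are the expected lengths (residues)
    of prion-state and background-state runs; they induce self-transition
    probabilities ``1 - 1/L`` and switching probabilities ``1/L``.
    """

    prion_run: float = 100.0
    background_run: float = 500.0

    def __post_init__(self) -> None:
        if self.prion_run <= 1 or self.background_run <= 1:
            raise ValueError("expected run lengths must exceed 1 residue")

    @property
    def _a_pp(self) -> float:
        return 1.0 - 1.0 / self.prion_run

    @property
    def _a_bb(self) -> float:
        return 1.0 - 1.0 / self.background_run

    def per_residue_adjust(self) -> float:
        """Natural-log odds, per in-run residue, of staying prion vs background."""
        return math.log(self._a_pp) - math.log(self._a_bb)

    def run_constant(self) -> float:
        """Natural-log constant cost of opening and closing one prion run."""
        return (
            math.log(1.0 / self.background_run)  # B -> P entry
            + math.log(1.0 / self.prion_run)     # P -> B exit
            - math.log(self._a_pp)
            - math.log(self._a_bb)
        )


@dataclass
class ScoreParams:
    """Frequency tables and structural parameters of the LLR scorer."""

    f_prion: dict[str, float]
    f_background: dict[str, float]
    log_base: float = math.e
    core_length: int = 60
    transition: TransitionParams = field(default_factory=TransitionParams)

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.core_length < 1:
            raise ValueError("core_length must be >= 1")
        self.f_prion = _normalise(self.f_prion)
        self.f_background = _normalise(self.f_background)
        ln_base = math.log(self.log_base)
        self._llr = {
            aa: (math.log(self.f_prion[aa]) - math.log(self.f_background[aa])) / ln_base
            for aa in AA20
        }
        for aa in AMBIGUOUS:
            self._llr[aa] = 0.0
        # byte-indexed lookup for vectorised scoring
        table = np.full(128, np.nan)
        for aa, v in self._llr.items():
            table[ord(aa)] = v
        self._llr_table = table
        self._ln_base = ln_base

    # -- derived quantities -------------------------------------------------

    def llr_of(self, residue: str) -> float:
        return self._llr[residue]

    def run_adjust(self) -> float:
        """Per-residue transition adjustment, in ``log_base`` units."""
        return self.transition.per_residue_adjust() / self._ln_base

    def run_constant(self) -> float:
        """Per-run open/close cost, in ``log_base`` units."""
        return self.transition.run_constant() / self._ln_base

    # -- construction / IO --------------------------------------------------

    @classmethod
    def default(cls) -> "ScoreParams":
        with resources.as_file(
            resources.files("prionscope").joinpath("data", "default_params.tsv")
        ) as p:
            return cls.from_file(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoreParams":
        """Read the flat key/value + table TSV parameter format."""
        f_p: dict[str, float] = {}
        f_b: dict[str, float] = {}
        scalars: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "f_P":
                f_p[parts[1]] = float(parts[2])
            elif parts[0] == "f_B":
                f_b[parts[1]] = float(parts[2])
            else:
                scalars[parts[0]] = float(parts[1])
        missing = [aa for aa in AA20 if aa not in f_p or aa not in f_b]
        if missing:
            raise ValueError(f"parameter file missing frequencies for: {missing}")
        return cls(
            f_prion=f_p,
            f_background=f_b,
            log_base=scalars.get("log_base", math.e),
            core_length=int(scalars.get("core_length", 60)),
            transition=TransitionParams(
                prion_run=scalars.get("prion_run", 100.0),
                background_run=scalars.get("background_run", 500.0),
            ),
        )

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"log_base\t{self.log_base!r}",
            f"core_length\t{self.core_length}",
            f"prion_run\t{self.transition.prion_run!r}",
            f"background_run\t{self.transition.background_run!r}",
        ]
        lines += [f"f_P\t{aa}\t{self.f_prion[aa]!r}" for aa in AA20]
        lines += [f"f_B\t{aa}\t{self.f_background[aa]!r}" for aa in AA20]
        Path(path).write_text("\n".join(lines) + "\n")
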
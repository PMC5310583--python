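"""Rate-matrix models for binary and paired-binary trait evolution.

The joint state space for two binary traits is ordered
``(0,0) -> 0, (0,1) -> 1, (1,0) -> 2, (1,1) -> 3`` where the pair is
``(trait1, trait2)``.  Simultaneous changes of both traits are structural
zeros: the chain moves one trait at a time.

Three model families are provided:

* ``mk2_model`` — a single binary trait with forward/backward rates.
* ``dependent_model`` — Pagel's dependent model: all eight single-trait
  transition rates free, so a trait's rate may depend on the other trait's
  current state.
* ``independent_model`` — the nested special case in which each trait's
  rates are identical regardless of the background state (four free rates);
  its generator is the Kronecker sum of the two single-trait generators.

``RateModel.constrain`` adds one rate-equality constraint, producing the
restricted models used in one-degree-of-freedom likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateModel",
    "mk2_model",
    "dependent_model",
    "independent_model",
    "build_q",
    "encode_pair",
    "decode_pair",
    "PAIR_STATES",
    "DEPENDENT_RATE_NAMES",
    "canonical_restrictions",
]

# joint-state encoding for (trait1, trait2)
PAIR_STATES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))
_PAIR_INDEX = {s: i for i, s in enumerate(PAIR_STATES)}


def encode_pair(s1: int, s2: int) -> int:
    """Combined state index of a (trait1, trait2) pair."""
    return _PAIR_INDEX[(int(s1), int(s2))]


def decode_pair(state: int) -> tuple[int, int]:
    return PAIR_STATES[state]


# the eight single-step transitions of the dependent model, named q<from><to>
DEPENDENT_RATE_NAMES = ("q01", "q02", "q10", "q13", "q20", "q23", "q31", "q32")


@dataclass(frozen=True)
class RateModel:
    """A Markov generator structure: which entries are free and how tied.

    ``entry_map`` assigns each allowed off-diagonal (i, j) a parameter name;
    entries absent from the map are structural zeros.  Several entries may
    share one name (equality constraint).  ``param_names`` fixes the
    parameter order used by vector-valued interfaces.
    """

    name: str
    n_states: int
    entry_map: dict[tuple[int, int], str]
    param_names: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def constrain(self, rate_a: str, rate_b: str, *, name: str | None = None) -> "RateModel":
        """Force two named rates equal; the merged parameter keeps ``rate_a``'s name."""
        for r in (rate_a, rate_b):
            if r not in self.param_names:
                raise KeyError(f"unknown rate name {r!r}; have {self.param_names}")
        if rate_a == rate_b:
            raise ValueError("cannot constrain a rate to itself")
        new_map = {
            ij: (rate_a if p == rate_b else p) for ij, p in self.entry_map.items()
        }
        new_names = tuple(p for p in self.param_names if p != rate_b)
        return RateModel(
            name=name or f"{self.name}[{rate_a}={rate_b}]",
            n_states=self.n_states,
            entry_map=new_map,
            param_names=new_names,
            meta=dict(self.meta, restriction=(rate_a, rate_b)),
        )

    def rates_dict(self, values) -> dict[str, float]:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_free,):
            raise ValueError(
                f"model {self.name!r} needs {self.n_free} rates, got shape {values.shape}"
            )
        return dict(zip(self.param_names, values))


def mk2_model() -> RateModel:
    """Two-state Mk model with separate gain (0->1) and loss (1->0) rates."""
    return RateModel(
        name="mk2",
        n_states=2,
        entry_map={(0, 1): "q01", (1, 0): "q10"},
        param_names=("q01", "q10"),
    )


def dependent_model() -> RateModel:
    """Pagel's dependent model: 8 free single-step rates on the 4-state chain."""
    entry_map = {
        (0, 1): "q01",
        (0, 2): "q02",
        (1, 0): "q10",
        (1, 3): "q13",
        (2, 0): "q20",
        (2, 3): "q23",
        (3, 1): "q31",
        (3, 2): "q32",
    }
    return RateModel(
        name="dependent",
        n_states=4,
        entry_map=entry_map,
        param_names=DEPENDENT_RATE_NAMES,
    )


def independent_model() -> RateModel:
    """Independent evolution of the two traits: 4 free rates.

    Trait 1 changes at rates (a01, a10) and trait 2 at (b01, b10)
    irrespective of the other trait's state, i.e. the dependent model with
    the four equalities q02=q13, q20=q31, q01=q23, q10=q32.
    """
    entry_map = {
        (0, 2): "a01",
        (1, 3): "a01",
        (2, 0): "a10",
        (3, 1): "a10",
        (0, 1): "b01",
        (2, 3): "b01",
        (1, 0): "b10",
        (3, 2): "b10",
    }
    return RateModel(
        name="independent",
        n_states=4,
        entry_map=entry_map,
        param_names=("a01", "a10", "b01", "b10"),
    )


def build_q(model: RateModel, rates) -> np.ndarray:
    """Instantaneous rate matrix from a rate vector or name->value mapping.

    Off-diagonals honour structural zeros and equality constraints; each
    diagonal entry is minus its row sum.  Rates must be non-negative (zero
    is allowed only through an explicit constraint or a deliberate zero).
    """
    if not isinstance(rates, dict):
        rates = model.rates_dict(rates)
    missing = set(model.param_names) - set(rates)
    if missing:
        raise ValueError(f"missing rates: {sorted(missing)}")
    Q = np.zeros((model.n_states, model.n_states))
    for (i, j), pname in model.entry_map.items():
        v = float(rates[pname])
        if v < 0:
            raise ValueError(f"rate {pname} is negative ({v})")
        Q[i, j] = v
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def canonical_restrictions(
    trait1: str = "iris", trait2: str = "nest"
) -> list[tuple[str, str, str]]:
    """The four one-equality restrictions of the dependent model.

    Each ties a trait-1 (or trait-2) transition rate across the two states
    of the background trait.  Labels are phrased for the iris-colour x
    cavity-nesting application by default (trait1 state 1 = bright iris,
    trait2 state 1 = cavity nesting) but the rate names are generic.

    Returns ``(label, rate_a, rate_b)`` triples; ``rate_a``/``rate_b`` index
    dependent-model rates.
    """
    return [
        (
            f"{trait1} 0->1 equal across {trait2} states",
            "q13",  # trait1 0->1 when trait2 = 1
            "q02",  # trait1 0->1 when trait2 = 0
        ),
        (
            f"{trait1} 1->0 equal across {trait2} states",
            "q31",
            "q20",
        ),
        (
            f"{trait2} 1->0 equal across {trait1} states",
            "q32",  # trait2 1->0 when trait1 = 1
            "q10",
        ),
        (
            f"{trait2} 0->1 equal across {trait1} states",
            "q23",
            "q01",
        ),
    ]
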
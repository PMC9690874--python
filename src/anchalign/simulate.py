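"""Synthetic families of similar DNA sequences.

Families emulate sets of related sequences produced by a Jukes–Cantor-style
evolutionary process: one uniform random root sequence, from which every
member is derived independently (a star topology).  Each member receives
``round(avg_distance / 2)`` mutation events, so the mutational path between
two members holds ~``avg_distance`` events — "average distance" is mapped
to the expected event count separating two family members.

An event is a substitution with probability ``1 - indel_prob`` (uniform
position, uniform different base — the Jukes–Cantor symmetric model) and
otherwise an insertion or deletion (equal odds) of geometric length.  The
defaults keep indels rare and short (indel_prob=0.05, mean length 2), the
regime in which related sequences align with few gaps — the setting the
anchored heuristic targets.

Presets name the four standard study conditions: families of 100
sequences with average length 100/200/300 at average distance 100 (h100,
h200, h300) and the less-diverse d50 (length 100, distance 50).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import floor, log
from random import Random

from .errors import ParameterError, StateError
from .store import Sequence

__all__ = ["FamilyParams", "PRESETS", "mutate_sequence", "generate_family"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FamilyParams:
    """Parameters of one generated family.

    ``avg_distance`` is the expected number of mutation events separating
    two members; ``indel_prob`` the fraction of events that are indels;
    ``indel_len_mean`` the geometric mean indel length (>= 1).
    """

    n_sequences: int = 100
    avg_length: int = 100
    avg_distance: int = 100
    indel_prob: float = 0.05
    indel_len_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ParameterError("n_sequences must be >= 2")
        if self.avg_length < 1:
            raise ParameterError("avg_length must be >= 1")
        if self.avg_distance < 0:
            raise ParameterError("avg_distance must be >= 0")
        if not 0 <= self.indel_prob < 1:
            raise ParameterError("indel_prob must be in [0, 1)")
        if self.indel_len_mean < 1:
            raise ParameterError("indel_len_mean must be >= 1")


PRESETS: dict[str, FamilyParams] = {
    "d50": FamilyParams(n_sequences=100, avg_length=100, avg_distance=50),
    "h100": FamilyParams(n_sequences=100, avg_length=100, avg_distance=100),
    "h200": FamilyParams(n_sequences=100, avg_length=200, avg_distance=100),
    "h300": FamilyParams(n_sequences=100, avg_length=300, avg_distance=100),
}


def _geometric(rng: Random, mean: float) -> int:
    """Geometric length on {1, 2, ...} with the given mean."""
    if mean <= 1:
        return 1
    p = 1.0 / mean
    u = rng.random()
    return 1 + floor(log(1.0 - u) / log(1.0 - p))


def mutate_sequence(
    seq: str,
    n_events: int,
    indel_prob: float = 0.05,
    indel_len_mean: float = 2.0,
    seed: int = 0,
) -> str:
    """Apply ``n_events`` i.i.d. mutation events to ``seq``.

    Substitution: uniform position, uniform different base.  Indel:
    insertion or deletion with equal odds, geometric length; deletions are
    clamped so the sequence never becomes empty.  Deterministic under
    ``seed``.
    """
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    if n_events > 0 and not seq:
        raise StateError("cannot mutate an empty sequence")
    rng = Random(seed)
    chars = list(seq)
    for _ in range(n_events):
        if rng.random() >= indel_prob:
            pos = rng.randrange(len(chars))
            chars[pos] = rng.choice(_BASES.replace(chars[pos], ""))
        else:
            length = _geometric(rng, indel_len_mean)
            if rng.random() < 0.5:  # insertion
                pos = rng.randrange(len(chars) + 1)
                chars[pos:pos] = rng.choices(_BASES, k=length)
            else:  # deletion, never below one remaining base
                length = min(length, len(chars) - 1)
                if length == 0:
                    continue
                pos = rng.randrange(len(chars) - length + 1)
                del chars[pos : pos + length]
    return "".join(chars)


def generate_family(params: FamilyParams) -> list[Sequence]:
    """Generate a family by independent derivation from one random root.

    Each member gets ``round(avg_distance / 2)`` events so two members are
    separated by ~``avg_distance`` events along the star.  Deterministic
    under ``params.seed``; never contains N.
    """
    master = Random(params.seed)
    root = "".join(master.choice(_BASES) for _ in range(params.avg_length))
    per_leaf = round(params.avg_distance / 2)
    width = len(str(params.n_sequences - 1))
    family = []
    for i in range(params.n_sequences):
        leaf_seed = master.getrandbits(31)
        seq = mutate_sequence(
            root,
            per_leaf,
            indel_prob=params.indel_prob,
            indel_len_mean=params.indel_len_mean,
            seed=leaf_seed,
        )
        family.append(Sequence(f"fam{i:0{width}d}", seq))
    return family


def preset_family(name: str, n_sequences: int | None = None, seed: int = 0):
    """A family from a named preset, optionally overriding size and seed."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = replace(PRESETS[name], seed=seed)
    if n_sequences is not None:
        params = replace(params, n_sequences=n_sequences)
    return generate_family(params)
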
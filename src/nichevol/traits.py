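"""Discrete character data: substrate-preference and niche-breadth coding.

Two characters drive every downstream analysis:

* **PS** — preferred substrate, a five-state character over the fixed
  alphabet ``rock, soil, bark, wood, lichen`` ("lichen" = other lichens used
  as substrate).  The alphabet is fixed even when some states are unobserved
  in a dataset, so that rate matrices and diversification parameter vectors
  stay comparable across datasets.
* **GS** — ecological strategy, binary ``generalist / specialist``.  A
  species is coded specialist when strictly more than 95% of its recorded
  occurrences come from a single substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PS_STATES",
    "GS_STATES",
    "CharacterData",
    "SamplingScheme",
    "GsCall",
    "classify_gs",
    "sampling_fractions",
    "complete_sampling",
    "read_character_table",
    "write_character_table",
    "characters_from_occurrences",
]

PS_STATES = ("rock", "soil", "bark", "wood", "lichen")
GS_STATES = ("generalist", "specialist")

#: default specialist threshold: strictly greater than 95% of occurrences
SPECIALIST_THRESHOLD = 0.95


class CharacterValidationError(ValueError):
    pass


@dataclass
class CharacterData:
    """A tip → state map over an explicit, ordered state space."""

    name: str
    states: tuple
    data: dict  # tip label -> state index

    def __post_init__(self):
        self.states = tuple(self.states)
        if len(self.states) < 2:
            raise CharacterValidationError("state space must have k >= 2")
        k = len(self.states)
        for tip, idx in self.data.items():
            if not 0 <= idx < k:
                raise CharacterValidationError(
                    f"tip {tip!r}: state index {idx} out of range for k={k}"
                )

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def tips(self) -> list:
        return list(self.data)

    def state_of(self, tip: str) -> str:
        return self.states[self.data[tip]]

    def state_vector(self, labels) -> np.ndarray:
        """Integer state indices in the given tip-label order."""
        try:
            return np.array([self.data[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise CharacterValidationError(
                f"tip {e.args[0]!r} has no character state"
            ) from None

    def counts(self) -> np.ndarray:
        c = np.zeros(self.k, dtype=np.int64)
        for idx in self.data.values():
            c[idx] += 1
        return c

    @classmethod
    def from_states(cls, name, states, tip_states: dict) -> "CharacterData":
        states = tuple(states)
        lookup = {s: i for i, s in enumerate(states)}
        data = {}
        for tip, s in tip_states.items():
            key = str(s).strip().lower()
            if key not in lookup:
                raise CharacterValidationError(
                    f"tip {tip!r}: unknown state {s!r}; allowed: {list(states)}"
                )
            data[tip] = lookup[key]
        return cls(name=name, states=states, data=data)


@dataclass
class SamplingScheme:
    """Per-state (or per-clade) fraction of described species that are sampled."""

    fractions: dict  # group name -> fraction in (0, 1]

    def __post_init__(self):
        for g, f in self.fractions.items():
            if not 0.0 < f <= 1.0:
                raise CharacterValidationError(
                    f"sampling fraction for {g!r} must be in (0, 1], got {f}"
                )

    def vector(self, groups) -> np.ndarray:
        return np.array([self.fractions[g] for g in groups])


@dataclass(frozen=True)
class GsCall:
    """Outcome of the specialist rule for one species."""

    strategy: str  # "generalist" or "specialist"
    preferred: str  # argmax / modal substrate
    share: float  # occurrence share of the preferred substrate
    tied: bool  # True when the modal substrate is not unique


def classify_gs(occurrences: dict, threshold: float = SPECIALIST_THRESHOLD) -> GsCall:
    """Apply the specialist rule to one species' occurrence counts.

    A species is a specialist iff the share of its most frequent substrate is
    *strictly* greater than ``threshold`` (default 0.95).  The preferred
    substrate is the argmax substrate; for generalists with tied modal counts
    the tie is flagged, not broken.
    """
    if not 0.0 < threshold < 1.0:
        raise CharacterValidationError(f"threshold must be in (0,1), got {threshold}")
    if any(v < 0 for v in occurrences.values()):
        raise CharacterValidationError("negative occurrence count")
    total = sum(occurrences.values())
    if total <= 0:
        raise CharacterValidationError("all-zero occurrence row")
    best = max(occurrences, key=lambda s: occurrences[s])
    share = occurrences[best] / total
    tied = sum(1 for v in occurrences.values() if v == occurrences[best]) > 1
    strategy = "specialist" if share > threshold else "generalist"
    return GsCall(strategy=strategy, preferred=best, share=share, tied=tied)


def sampling_fractions(included: dict, known: dict) -> SamplingScheme:
    """Ratios of included to described species per group."""
    fr = {}
    for g in known:
        inc = included.get(g, 0)
        if known[g] <= 0:
            raise CharacterValidationError(f"group {g!r}: known count must be > 0")
        if inc > known[g]:
            raise CharacterValidationError(
                f"group {g!r}: included ({inc}) exceeds known ({known[g]})"
            )
        if inc <= 0:
            raise CharacterValidationError(
                f"group {g!r}: no species included; state unobservable"
            )
        fr[g] = inc / known[g]
    return SamplingScheme(fr)


def complete_sampling(groups=PS_STATES) -> SamplingScheme:
    """The 100%-sampling scenario: every fraction exactly 1."""
    return SamplingScheme({g: 1.0 for g in groups})


# ---------------------------------------------------------------------------
# Tables


def characters_from_occurrences(
    table: pd.DataFrame, threshold: float = SPECIALIST_THRESHOLD
) -> tuple[CharacterData, CharacterData, pd.DataFrame]:
    """Derive PS and GS characters from a per-species occurrence-count table.

    ``table`` is indexed by species with one column per PS state.  Returns
    ``(ps, gs, detail)`` where ``detail`` records share and tie flags.
    """
    ps_states = {}
    gs_states = {}
    rows = []
    for sp, row in table.iterrows():
        call = classify_gs({s: int(row.get(s, 0)) for s in PS_STATES}, threshold)
        ps_states[sp] = call.preferred
        gs_states[sp] = call.strategy
        rows.append(
            {"species": sp, "ps_state": call.preferred, "gs_state": call.strategy,
             "share": call.share, "modal_tie": call.tied}
        )
    ps = CharacterData.from_states("PS", PS_STATES, ps_states)
    gs = CharacterData.from_states("GS", GS_STATES, gs_states)
    return ps, gs, pd.DataFrame(rows).set_index("species")


def read_character_table(path, sep=None):
    """Read a species/ps_state/gs_state table (CSV or TSV, header required).

    Returns ``(ps, gs)`` :class:`CharacterData` objects on the fixed state
    spaces.  State names are case-insensitive on input.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "species" not in df.columns:
        raise CharacterValidationError("character table needs a 'species' column")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise CharacterValidationError(f"duplicated species rows: {dupes}")
    df = df.set_index("species")
    ps = gs = None
    if "ps_state" in df.columns:
        ps = CharacterData.from_states("PS", PS_STATES, df["ps_state"].to_dict())
    if "gs_state" in df.columns:
        gs = CharacterData.from_states("GS", GS_STATES, df["gs_state"].to_dict())
    if ps is None and gs is None:
        raise CharacterValidationError(
            "character table needs a 'ps_state' and/or 'gs_state' column"
        )
    return ps, gs


def write_character_table(path, ps: CharacterData = None, gs: CharacterData = None,
                          sep=","):
    """Write PS/GS characters back to a CSV/TSV with canonical lowercase states."""
    if ps is None and gs is None:
        raise ValueError("nothing to write")
    tips = (ps or gs).tips
    out = pd.DataFrame({"species": tips})
    if ps is not None:
        out["ps_state"] = [ps.state_of(t) for t in tips]
    if gs is not None:
        out["gs_state"] = [gs.state_of(t) for t in tips]
    out.to_csv(path, sep=sep, index=False)


def check_tip_concordance(tree_labels, data: CharacterData):
    """Report tips present in only one of tree / character table."""
    tree_set = set(tree_labels)
    data_set = set(data.tips)
    return sorted(tree_set - data_set), sorted(data_set - tree_set)
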
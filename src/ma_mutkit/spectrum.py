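"""The six strand-collapsed substitution classes.

Substitutions are keyed by the ancestral base pair (A:T vs G:C origin) and
collapsed over strands, giving six classes. ``DERIVED_BASE`` maps
(ancestral base, class) -> derived base consistent with the collapsing.
"""

from __future__ import annotations

SPECTRUM_CLASSES = [
    "A:T>C:G",
    "A:T>G:C",
    "A:T>T:A",
    "G:C>A:T",
    "G:C>C:G",
    "G:C>T:A",
]

# base codes: A=0, C=1, G=2, T=3
AT_BASES = (0, 3)
GC_BASES = (1, 2)

# (anc_code, class_index) -> derived base code
DERIVED_BASE = {
    (0, 0): 1, (0, 1): 2, (0, 2): 3,   # A -> C, G, T
    (3, 0): 2, (3, 1): 1, (3, 2): 0,   # T -> G, C, A
    (2, 3): 0, (2, 4): 1, (2, 5): 3,   # G -> A, C, T
    (1, 3): 3, (1, 4): 2, (1, 5): 0,   # C -> T, G, A
}

_COLLAPSE = {(a, d): c for (a, c), d in DERIVED_BASE.items()}


def classes_for_base(anc_code: int) -> list[int]:
    """The three class indices available to an ancestral base."""
    return [0, 1, 2] if anc_code in AT_BASES else [3, 4, 5]


def collapse_type(anc_code: int, derived_code: int) -> int:
    """Class index (0..5) of a substitution, or raise on identity."""
    try:
        return _COLLAPSE[(int(anc_code), int(derived_code))]
    except KeyError:
        raise ValueError(
            f"not a substitution: anc={anc_code} derived={derived_code}"
        ) from None
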
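"""Helpers shared across test modules."""

from __future__ import annotations

from csmomics.datatypes import PairSet


def make_pairs(n: int) -> PairSet:
    """A trivial PairSet over subjects C{i} (cases) / K{i} (controls)."""
    return PairSet(pairs=[(f"C{i}", f"K{i}", float("nan")) for i in range(n)])
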
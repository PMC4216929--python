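"""Repeat motif handling.

An STR motif is the repeated unit of a tandem repeat, 1-6 bp long. Because a
repeat tract can be read in any phase and on either strand, motifs are
aggregated under a canonical representative: the lexicographically smallest
string among all cyclic rotations of the motif and of its reverse complement,
reduced to its primitive (non-self-repetitive) unit. E.g. "CA", "TG", "GT"
and "AC" all canonicalize to "AC"; "ACAC" reduces to "AC".
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

MAX_PERIOD = 6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(seq: str) -> list[str]:
    """All cyclic rotations of ``seq``."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def primitive_unit(seq: str) -> str:
    """Smallest unit whose exact repetition equals ``seq``.

    "ACAC" -> "AC"; "ACG" -> "ACG".
    """
    n = len(seq)
    for d in range(1, n + 1):
        if n % d == 0 and seq == seq[:d] * (n // d):
            return seq[:d]
    return seq  # unreachable


def is_primitive(seq: str) -> bool:
    return primitive_unit(seq) == seq


def strand_canonical(seq: str) -> str:
    """Lexicographically smallest rotation of the primitive unit.

    Unlike :func:`canonical_motif` this does not fold the reverse complement,
    so it identifies the motif as read on the given strand ("GT" stays "GT").
    Used when scoring and merging candidate repeats, where strand matters.
    """
    unit = primitive_unit(seq)
    return min(rotations(unit))


def canonical_motif(seq: str) -> str:
    """Canonical representative of a motif.

    Minimum over all cyclic rotations of the primitive unit and of its
    reverse complement. Idempotent, identical for every rotation and for
    the reverse complement.

    Raises
    ------
    ValueError
        If ``seq`` is empty, longer than 6 bp, or contains non-ACGT bases.
    """
    if not 1 <= len(seq) <= MAX_PERIOD:
        raise ValueError(f"motif length must be 1-{MAX_PERIOD}, got {len(seq)}")
    if not _ALPHABET.issuperset(seq):
        raise ValueError(f"motif contains non-ACGT characters: {seq!r}")
    unit = primitive_unit(seq)
    return min(min(rotations(unit)), min(rotations(reverse_complement(unit))))


def all_canonical_motifs(period: int) -> list[str]:
    """Every canonical motif of exactly the given period (useful for enumeration)."""
    import itertools

    out = set()
    for tup in itertools.product("ACGT", repeat=period):
        s = "".join(tup)
        if is_primitive(s):
            c = canonical_motif(s)
            if len(c) == period:
                out.add(c)
    return sorted(out)
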
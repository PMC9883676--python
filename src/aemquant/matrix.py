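"""Design-matrix container shared by the simulator and the X-builder.

The design matrix ``X`` of one transcription cluster maps isoform abundances
``beta`` to expected equivalence-class read counts via ``mu = X @ beta``.
Rows are binary occupancy patterns (which transcripts receive reads from an
equivalence class), columns are transcripts (or merged paralog groups), and
every column sums to one — the identifiability constraint that fixes the
scale of each column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DesignMatrix", "ParalogGroup", "pattern_string"]

COLSUM_TOL = 1e-9


def pattern_string(bits: tuple[int, ...]) -> str:
    """Render an occupancy pattern as a bit string, e.g. ``(1,1,0,1) -> '1101'``."""
    return "".join("1" if b else "0" for b in bits)


@dataclass(frozen=True)
class ParalogGroup:
    """A set of transcripts collapsed into one design-matrix column.

    Paralogs have (near-)collinear columns, which makes the matrix singular
    and the individual abundances non-identifiable; the group records which
    transcripts were merged and the singular-value spectrum that triggered it.
    """

    members: frozenset[str]
    singular_values: tuple[float, ...]
    sv_threshold: float = 0.02

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a paralog group needs at least two members")

    @property
    def merged_id(self) -> str:
        return "+".join(sorted(self.members))


@dataclass
class DesignMatrix:
    """Occupancy patterns x transcripts matrix of read-allocation proportions.

    Attributes
    ----------
    transcripts
        Column identifiers. Merged paralog groups use ``id1+id2`` names.
    patterns
        One binary tuple per row, indexed like ``transcripts``. A set bit
        means the column's transcript receives reads from that class.
    x
        ``(J, T)`` array of proportions; each column sums to 1 and is zero
        wherever the pattern bit is zero.
    merged_groups
        Paralog groups that were collapsed into single columns, if any.
    """

    transcripts: list[str]
    patterns: list[tuple[int, ...]]
    x: np.ndarray
    merged_groups: list[ParalogGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.patterns), len(self.transcripts)):
            raise ValueError(
                f"x has shape {self.x.shape}, expected "
                f"({len(self.patterns)}, {len(self.transcripts)})"
            )
        if len(set(self.transcripts)) != len(self.transcripts):
            raise ValueError("duplicate transcript ids")
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("duplicate occupancy patterns")

    # -- structure ---------------------------------------------------------
    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def mask(self) -> np.ndarray:
        """Boolean ``(J, T)`` occupancy mask."""
        return np.array(self.patterns, dtype=bool)

    def pattern_strings(self) -> list[str]:
        return [pattern_string(p) for p in self.patterns]

    def pattern_sets(self) -> list[frozenset[str]]:
        """Each row as the set of column ids with a set bit."""
        return [
            frozenset(t for t, b in zip(self.transcripts, bits) if b)
            for bits in self.patterns
        ]

    def member_to_column(self) -> dict[str, int]:
        """Map every original transcript id to its column index.

        Members of merged groups map to the merged column.
        """
        out: dict[str, int] = {}
        for j, tid in enumerate(self.transcripts):
            for member in tid.split("+"):
                out[member] = j
        return out

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check column sums and zero-pattern consistency; raise on violation."""
        if np.any(self.x < -COLSUM_TOL):
            raise ValueError("negative entries in design matrix")
        colsums = self.x.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=COLSUM_TOL):
            raise ValueError(f"column sums deviate from 1: {colsums}")
        if np.any(self.x[~self.mask] != 0):
            raise ValueError("nonzero entry outside the occupancy pattern")

    # -- construction helpers ---------------------------------------------
    def copy(self) -> "DesignMatrix":
        return DesignMatrix(
            list(self.transcripts),
            list(self.patterns),
            self.x.copy(),
            list(self.merged_groups),
        )

    @staticmethod
    def block_diag(blocks: list["DesignMatrix"]) -> "DesignMatrix":
        """Stack per-cluster design matrices into one block-diagonal matrix.

        Useful for treating a multi-cluster experiment as a single system;
        patterns from different clusters have disjoint support and therefore
        stay unique.
        """
        if not blocks:
            raise ValueError("no blocks to combine")
        transcripts: list[str] = []
        for b in blocks:
            transcripts.extend(b.transcripts)
        offsets = np.cumsum([0] + [b.n_transcripts for b in blocks])
        total_t = offsets[-1]
        patterns: list[tuple[int, ...]] = []
        rows: list[np.ndarray] = []
        groups: list[ParalogGroup] = []
        for b, off in zip(blocks, offsets):
            groups.extend(b.merged_groups)
            for bits, xrow in zip(b.patterns, b.x):
                full_bits = [0] * total_t
                full_row = np.zeros(total_t)
                full_bits[off : off + b.n_transcripts] = list(bits)
                full_row[off : off + b.n_transcripts] = xrow
                patterns.append(tuple(full_bits))
                rows.append(full_row)
        return DesignMatrix(transcripts, patterns, np.array(rows), groups)
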
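"""Two-component scoring of nonsynonymous substitutions.

Component 1 — physicochemical change: normalized distance between the two
amino acids under a pluggable symmetric matrix (default: Grantham), mapped
to [0, 1] with 0 = identity (neutral).

Component 2 — sequence conservation at the substituted residue, from an
ortholog alignment column: identity fraction to the reference residue by
default, or one minus normalized Shannon entropy. Both in [0, 1] with
higher = more conserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .effects import NONSYNONYMOUS_LIKE, STOP, SubstitutionEffect
from .grantham import AMINO_ACIDS, GRANTHAM, GRANTHAM_MAX

logger = logging.getLogger(__name__)

GAP_CHARS = ("-", ".")

CONSERVATION_METHODS = ("identity", "entropy")


class SubstitutionMatrix:
    """Symmetric nonnegative amino-acid distance table with zero diagonal."""

    def __init__(self, distances: Mapping[Tuple[str, str], float]):
        self._d = dict(distances)
        for (a, b), d in self._d.items():
            if d < 0:
                raise ValueError(f"negative distance for {a}/{b}")
            if a == b and d != 0:
                raise ValueError(f"nonzero diagonal for {a}")
            if self._d.get((b, a), d) != d:
                raise ValueError(f"asymmetric entries for {a}/{b}")
        self.max = max(self._d.values())
        if self.max <= 0:
            raise ValueError("matrix has no positive distances")

    def __call__(self, a: str, b: str) -> float:
        try:
            return self._d[(a, b)]
        except KeyError:
            raise KeyError(f"no distance for pair {a!r}/{b!r}") from None

    @classmethod
    def grantham(cls) -> "SubstitutionMatrix":
        return cls(GRANTHAM)

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionMatrix":
        """Load a 20x20 symmetric matrix: header row/column of amino acids."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        distances: Dict[Tuple[str, str], float] = {}
        for a in df.index:
            for b in df.columns:
                distances[(str(a), str(b))] = float(df.loc[a, b])
        return cls(distances)


def physchem_score(
    ref_aa: str,
    alt_aa: str,
    matrix: Optional[SubstitutionMatrix] = None,
) -> float:
    """Normalized physicochemical distance in [0, 1]; 0 for identity."""
    if STOP in (ref_aa, alt_aa):
        raise ValueError("stop codons are not scorable (handled upstream)")
    if matrix is None:
        matrix = SubstitutionMatrix.grantham()
    return matrix(ref_aa, alt_aa) / matrix.max


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of an ortholog protein alignment."""

    symbols: Tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("empty alignment column")

    @property
    def non_gap(self) -> Tuple[str, ...]:
        return tuple(s for s in self.symbols if s not in GAP_CHARS)


def conservation_score(
    column: AlignmentColumn,
    method: str = "identity",
) -> Optional[float]:
    """Conservation of an alignment column in [0, 1]; None for all-gap
    columns (flagged absent, never 0)."""
    if method not in CONSERVATION_METHODS:
        raise ValueError(f"method must be one of {CONSERVATION_METHODS}")
    residues = column.non_gap
    if not residues:
        return None
    if method == "identity":
        return sum(1 for r in residues if r == column.reference) / len(residues)
    counts: Dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    total = len(residues)
    entropy = -sum((c / total) * math.log(c / total) for c in counts.values())
    return 1.0 - entropy / math.log(20)


@dataclass(frozen=True)
class EffectScore:
    """The two score components for one substitution; ``conservation`` is
    None when no usable alignment column exists."""

    physchem: float
    conservation: Optional[float]


def column_for_residue(
    alignment: Mapping[str, str],
    residue_index: int,
    reference_aa: str,
) -> Optional[AlignmentColumn]:
    """Extract the alignment column for a 1-based residue index; None when
    the index exceeds the alignment length."""
    rows = list(alignment.values())
    if not rows or residue_index < 1 or residue_index > len(rows[0]):
        return None
    symbols = tuple(row[residue_index - 1] for row in rows)
    return AlignmentColumn(symbols=symbols, reference=reference_aa)


def score_substitutions(
    effects: Sequence[SubstitutionEffect],
    alignments: Mapping[str, Mapping[str, str]],
    matrix: Optional[SubstitutionMatrix] = None,
    conservation_method: str = "identity",
) -> List[Tuple[SubstitutionEffect, EffectScore]]:
    """Score nonsynonymous substitutions; input order preserved.

    ``alignments`` maps gene id -> aligned rows. Effects without an
    alignment (or whose residue lies beyond it) get a conservation of None.
    Synonymous effects are rejected.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.grantham()
    out: List[Tuple[SubstitutionEffect, EffectScore]] = []
    for effect in effects:
        if effect.status not in NONSYNONYMOUS_LIKE:
            raise ValueError(
                f"effect {effect.label} in {effect.gene_id} is {effect.status}; "
                "only nonsynonymous-like effects are scorable"
            )
        if effect.status == "nonsynonymous":
            pc = physchem_score(effect.ref_aa, effect.alt_aa, matrix)
        else:
            # nonsense / start-loss: maximal physicochemical disruption
            pc = 1.0
        cons: Optional[float] = None
        alignment = alignments.get(effect.gene_id)
        if alignment:
            column = column_for_residue(alignment, effect.residue_index, effect.ref_aa)
            if column is None:
                logger.warning(
                    "residue %d of %s beyond alignment; conservation absent",
                    effect.residue_index,
                    effect.gene_id,
                )
            else:
                cons = conservation_score(column, conservation_method)
        out.append((effect, EffectScore(physchem=pc, conservation=cons)))
    return out


def load_alignment_dir(path) -> Dict[str, Dict[str, str]]:
    """Load every aligned FASTA (``<gene_id>.afa``/``.fa``/``.fasta``) in a
    directory, keyed by gene id (file stem)."""
    from .genome_io import read_alignment

    out: Dict[str, Dict[str, str]] = {}
    p = Path(path)
    if not p.is_dir():
        return out
    for f in sorted(p.iterdir()):
        if f.suffix.lower() in (".afa", ".fa", ".fasta", ".aln"):
            out[f.stem] = read_alignment(f)
    return out
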
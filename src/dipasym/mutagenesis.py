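"""Random gene mutagenesis, translation, and wild-type/mutant comparison.

Tests whether random events at the gene level (base deletions, which
frameshift everything downstream, and base substitutions) reshape the
dipeptide statistics of the translated proteins.  Mutant translations are
pooled across genes and mutants before computing statistics, exactly as a
natural sequence set would be pooled.

Translation is frame 1, forward strand, standard genetic code; stop codons
emit '*' and translation continues to the end of the sequence (the
behaviour of classic batch translators), with trailing 1-2 bases dropped.
The counting stage treats '*' as a hard separator, so no dipeptide ever
spans a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .asymmetry import (
    PAIR_LABELS,
    AsymmetryTable,
    PropensityTable,
    pair_c190_vector,
)
from .counting import DipeptideCountTable, count_pairs
from .sequence_io import CodingSequence, ProteinSequence, SequenceSet

_BASES = "ACGT"
_BASE_TO_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MutationSpec:
    """One mutagenesis scheme: kind, events per mutant, mutants per gene."""

    kind: str               # "delete" or "substitute"
    n_events: int           # bases affected per mutant
    n_mutants: int = 100    # mutants generated per gene

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "substitute"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.n_events < 0 or (self.kind == "delete" and self.n_events < 1):
            raise ValueError("n_events must be >= 1 (>= 0 only for substitutions)")
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")

    @property
    def label(self) -> str:
        return f"{'del' if self.kind == 'delete' else 'sub'}{self.n_events}"


def standard_specs(n_mutants: int = 100) -> List[MutationSpec]:
    """The four standard schemes: delete 1, delete 5, substitute 10, substitute 50."""
    return [
        MutationSpec("delete", 1, n_mutants),
        MutationSpec("delete", 5, n_mutants),
        MutationSpec("substitute", 10, n_mutants),
        MutationSpec("substitute", 50, n_mutants),
    ]


def delete_bases(
    cds: CodingSequence, k: int, rng: np.random.Generator
) -> CodingSequence:
    """Remove k distinct uniformly chosen positions, preserving order."""
    n = len(cds.bases)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")
    positions = rng.choice(n, size=k, replace=False)
    arr = np.frombuffer(cds.bases.encode("ascii"), dtype=np.uint8)
    arr = np.delete(arr, positions)
    return CodingSequence(cds.id, arr.tobytes().decode("ascii"))


def substitute_bases(
    cds: CodingSequence, k: int, rng: np.random.Generator
) -> CodingSequence:
    """Replace k distinct uniformly chosen positions, each by one of the 3
    other bases chosen uniformly; k = 0 is the identity (internal test hook)."""
    n = len(cds.bases)
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= {n}")
    if k == 0:
        return CodingSequence(cds.id, cds.bases)
    positions = rng.choice(n, size=k, replace=False)
    idx = np.array([_BASE_TO_INDEX[b] for b in cds.bases], dtype=np.int64)
    # old + 1..3 (mod 4) enumerates exactly the three alternative bases
    idx[positions] = (idx[positions] + rng.integers(1, 4, size=k)) % 4
    out = "".join(_BASES[i] for i in idx)
    return CodingSequence(cds.id, out)


def translate(cds: CodingSequence) -> ProteinSequence:
    """Frame-1 standard-code translation; '*' at stops; trailing bases dropped.

    A sequence shorter than 3 bases yields an empty protein.
    """
    n = len(cds.bases) - len(cds.bases) % 3
    if n == 0:
        return ProteinSequence(cds.id, "")
    return ProteinSequence(cds.id, str(Seq(cds.bases[:n]).translate()))


@dataclass
class MutationExperimentResult:
    """Wild-type vs pooled-mutant dipeptide statistics, one entry per scheme."""

    wild_type_counts: DipeptideCountTable
    wild_type: Tuple[AsymmetryTable, PropensityTable]
    wild_type_translations: SequenceSet
    per_spec_counts: Dict[str, DipeptideCountTable]
    per_spec: Dict[str, Tuple[AsymmetryTable, PropensityTable]]
    translations: Dict[str, SequenceSet]
    c190_deltas: pd.DataFrame        # index pair (190), one column per spec label
    propensity_deltas: pd.DataFrame  # index ordered pair (400), one column per spec
    seed: int


def _stats(counts: DipeptideCountTable) -> Tuple[AsymmetryTable, PropensityTable]:
    return AsymmetryTable.from_counts(counts), PropensityTable.from_counts(counts)


def mutation_experiment(
    genes: Sequence[CodingSequence],
    specs: Sequence[MutationSpec],
    seed: int,
) -> MutationExperimentResult:
    """Run the full wild-type vs mutants comparison.

    For each scheme, ``n_mutants`` mutants are generated per gene from a
    single seeded random stream, translated, pooled across all genes and
    mutants, and their asymmetry and propensity tables computed.  Deltas are
    mutant minus wild type, NaN where either side is undefined.  The same
    seed reproduces the result bit for bit.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene set must be non-empty")
    max_delete = max(
        (s.n_events for s in specs if s.kind == "delete"), default=0
    )
    shortest = min(len(g) for g in genes)
    if max_delete >= shortest:
        raise ValueError(
            f"delete n_events {max_delete} is not below the shortest gene ({shortest})"
        )

    rng = np.random.default_rng(seed)
    wt_translations = SequenceSet(
        [translate(g) for g in genes], label="wild_type"
    )
    wt_counts = count_pairs(wt_translations)
    wt_at, wt_pt = _stats(wt_counts)
    wt_c190 = pair_c190_vector(wt_counts.counts.reshape(-1))

    per_spec_counts: Dict[str, DipeptideCountTable] = {}
    per_spec: Dict[str, Tuple[AsymmetryTable, PropensityTable]] = {}
    translations: Dict[str, SequenceSet] = {}
    c190_deltas = pd.DataFrame(index=PAIR_LABELS)
    prop_deltas = pd.DataFrame(index=wt_pt.to_frame().index)

    for spec in specs:
        mutate = delete_bases if spec.kind == "delete" else substitute_bases
        members = []
        for gene in genes:
            for j in range(spec.n_mutants):
                mutant = mutate(gene, spec.n_events, rng)
                prot = translate(mutant)
                members.append(
                    ProteinSequence(f"{gene.id}|{spec.label}|m{j}", prot.residues)
                )
        pooled = SequenceSet(members, label=spec.label)
        counts = count_pairs(pooled)
        at, pt = _stats(counts)
        per_spec_counts[spec.label] = counts
        per_spec[spec.label] = (at, pt)
        translations[spec.label] = pooled
        c190_deltas[spec.label] = (
            pair_c190_vector(counts.counts.reshape(-1)) - wt_c190
        )
        prop_deltas[spec.label] = (
            pt.to_frame()["propensity"] - wt_pt.to_frame()["propensity"]
        )

    return MutationExperimentResult(
        wild_type_counts=wt_counts,
        wild_type=(wt_at, wt_pt),
        wild_type_translations=wt_translations,
        per_spec_counts=per_spec_counts,
        per_spec=per_spec,
        translations=translations,
        c190_deltas=c190_deltas,
        propensity_deltas=prop_deltas,
        seed=seed,
    )


def experiment_report(result: MutationExperimentResult, decimals: int = 2) -> pd.DataFrame:
    """Per-pair report: wild-type c190, one c190 column per scheme, and deltas."""
    frame = pd.DataFrame(index=PAIR_LABELS)
    frame["wild_type"] = pair_c190_vector(
        result.wild_type_counts.counts.reshape(-1)
    )
    for label, counts in result.per_spec_counts.items():
        frame[label] = pair_c190_vector(counts.counts.reshape(-1))
        frame[f"delta_{label}"] = result.c190_deltas[label]
    frame.index.name = "pair"
    return frame.round(decimals)
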
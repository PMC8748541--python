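"""Read QC, codon-aware substitution calling, and count tables.

Reads are full-length, gapless copies of the reference ORF (pre-aligned input
is accepted as plain sequences of matching length). Calling is codon-wise:
the read and the reference are translated codon by codon and differing
residues are reported as substitutions in canonical numbering. Synonymous
changes yield nothing; stop gains are reported with alt ``'*'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import CodingSequence, substitution_key
from .synth import ReadSet, SubKey, _CODONS

logger = logging.getLogger(__name__)

DEFAULT_MIN_READ_QUALITY = 30.0
DEFAULT_MIN_MUTATION_COUNT = 10


@dataclass(frozen=True)
class PipelineConfig:
    """Filtering thresholds for the read-to-counts stage."""

    min_read_quality: float = DEFAULT_MIN_READ_QUALITY
    min_mutation_count: int = DEFAULT_MIN_MUTATION_COUNT
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if self.min_read_quality < 0 or self.min_mutation_count < 0:
            raise ValueError("thresholds must be >= 0")


def filter_reads_by_quality(reads: ReadSet, min_read_quality: float = DEFAULT_MIN_READ_QUALITY) -> ReadSet:
    """Keep reads whose *mean* Phred quality is >= the threshold.

    The boundary is inclusive: a read at exactly the threshold survives.
    """
    if len(reads) == 0:
        return ReadSet(pool=reads.pool, replicate=reads.replicate, bases=[],
                       qualities=[], provenance=dict(reads.provenance))
    means = reads.mean_qualities()
    keep = means >= min_read_quality
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("quality filter (%s, rep %d): discarded %d/%d reads below mean Q%g",
                    reads.pool, reads.replicate, n_drop, len(reads), min_read_quality)
    prov = dict(reads.provenance)
    prov["reads_discarded_by_quality"] = n_drop
    return ReadSet(
        pool=reads.pool,
        replicate=reads.replicate,
        bases=[b for b, k in zip(reads.bases, keep) if k],
        qualities=[q for q, k in zip(reads.qualities, keep) if k],
        provenance=prov,
    )


def call_substitutions(read: str, reference: CodingSequence) -> list[SubKey]:
    """Codon-wise amino-acid substitution calls for one gapless read.

    Raises ``ValueError`` on a length mismatch (the gapless contract).
    """
    if len(read) != len(reference):
        raise ValueError(
            f"read length {len(read)} != reference length {len(reference)} "
            "(gapless calling requires full-length reads)"
        )
    ref_nt = reference.nucleotides
    out: list[SubKey] = []
    for ci in range(reference.n_codons):
        ref_codon = ref_nt[ci * 3 : ci * 3 + 3]
        alt_codon = read[ci * 3 : ci * 3 + 3]
        if alt_codon == ref_codon:
            continue
        aa_ref = _CODONS[ref_codon]
        aa_alt = _CODONS.get(alt_codon)
        if aa_alt is None or aa_alt == aa_ref:
            continue
        out.append((reference.canonical(ci + 1), aa_ref, aa_alt))
    return out


class MutationCountTable:
    """Per-substitution read counts for one replicate's input/sorted pools.

    Wraps a DataFrame indexed by (position, ref, alt) with columns
    ``count_input`` and ``count_sorted``; ``totals`` holds the number of
    QC-passing reads per pool.
    """

    def __init__(self, df: pd.DataFrame, totals: dict[str, int], replicate: int = 1):
        if (df[["count_input", "count_sorted"]] < 0).any().any():
            raise ValueError("counts must be >= 0")
        self.df = df.sort_index()
        self.totals = dict(totals)
        self.replicate = replicate

    def __len__(self) -> int:
        return len(self.df)

    @property
    def substitutions(self) -> list[SubKey]:
        return list(self.df.index)

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.insert(0, "substitution",
                   [substitution_key(p, r, a) for p, r, a in self.df.index])
        out.to_csv(path, sep="\t", index=False)


def build_count_table(
    input_reads: ReadSet,
    sorted_reads: ReadSet,
    reference: CodingSequence,
    replicate: int = 1,
) -> MutationCountTable:
    """Tally per-substitution counts per pool; a read with k substitutions
    increments k rows. Length-mismatched reads are rejected with a log line.
    """
    counts: dict[SubKey, list[int]] = {}
    totals = {}
    for col, reads in (("count_input", input_reads), ("count_sorted", sorted_reads)):
        n_ok = 0
        n_bad = 0
        j = 0 if col == "count_input" else 1
        for b in reads.bases:
            try:
                subs = call_substitutions(b, reference)
            except ValueError:
                n_bad += 1
                continue
            n_ok += 1
            for s in subs:
                counts.setdefault(s, [0, 0])[j] += 1
        if n_bad:
            logger.info("%s pool: rejected %d length-mismatched reads", reads.pool, n_bad)
        totals[col.replace("count_", "")] = n_ok
    if counts:
        idx = pd.MultiIndex.from_tuples(sorted(counts), names=["position", "ref", "alt"])
        df = pd.DataFrame(
            {
                "count_input": [counts[s][0] for s in sorted(counts)],
                "count_sorted": [counts[s][1] for s in sorted(counts)],
            },
            index=idx,
        )
    else:
        idx = pd.MultiIndex.from_arrays([[], [], []], names=["position", "ref", "alt"])
        df = pd.DataFrame({"count_input": [], "count_sorted": []}, index=idx, dtype=int)
    return MutationCountTable(df, totals, replicate=replicate)


def apply_count_threshold(
    table: MutationCountTable, min_mutation_count: int = DEFAULT_MIN_MUTATION_COUNT
) -> MutationCountTable:
    """Drop substitutions seen fewer than ``min_mutation_count`` times in the
    replicate's pooled input+sorted counts. A row at exactly the threshold
    survives. Pool totals are unchanged.
    """
    if min_mutation_count < 0:
        raise ValueError("min_mutation_count must be >= 0")
    total = table.df["count_input"] + table.df["count_sorted"]
    kept = table.df[total >= min_mutation_count]
    n_drop = len(table.df) - len(kept)
    if n_drop:
        logger.info("count threshold %d: discarded %d/%d substitutions",
                    min_mutation_count, n_drop, len(table.df))
    return MutationCountTable(kept, table.totals, replicate=table.replicate)


def call_reads(reads: ReadSet, reference: CodingSequence) -> list[list[SubKey] | None]:
    """Substitution calls per read; None marks a rejected (length-mismatch) read."""
    out: list[list[SubKey] | None] = []
    for b in reads.bases:
        try:
            out.append(call_substitutions(b, reference))
        except ValueError:
            out.append(None)
    return out
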
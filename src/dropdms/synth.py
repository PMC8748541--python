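"""Synthetic droplet-screen generator.

Emulates the statistical structure of a droplet-microfluidic deep mutational
scan of an enzyme library:

* an error-prone PCR library with a Poisson number of random nucleotide
  substitutions per gene copy (~4.5 by default, yielding mostly 2-4 amino
  acid substitutions per variant);
* a latent activity model: each variant is active with probability
  ``logistic(beta0 + sum of per-substitution coefficients)``, with the
  intercept calibrated so a target fraction (~25% by default) of the library
  is active, and premature stop codons forced inactive;
* Poisson cell loading of droplets at ~10% occupancy, per-droplet
  fluorescence accumulation with lognormal expression noise and Gaussian
  autofluorescence, and a hard fluorescence gate whose passing droplets
  contribute *all* resident cells to the sorted pool (co-encapsulation is the
  built-in false-positive mechanism);
* full-length reads with i.i.d. per-base substitution errors and matching
  Phred qualities, serializable to FASTQ.

Every operation takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .sequences import STOP, CodingSequence, substitution_key, translate_codons

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"

SubKey = tuple[int, str, str]  # (canonical position, ref residue, alt residue)


@dataclass(frozen=True)
class VariantRecord:
    """One mutagenized gene variant with optional latent activity."""

    variant_id: str
    nt_substitutions: tuple[tuple[int, str, str], ...]  # 1-based construct nt pos
    aa_substitutions: tuple[SubKey, ...]  # canonical numbering
    true_activity_prob: float | None = None
    is_active: bool | None = None

    @property
    def has_stop_gain(self) -> bool:
        return any(alt == STOP for _, _, alt in self.aa_substitutions)


@dataclass
class VariantLibrary:
    """A set of variants of one reference coding sequence."""

    reference: CodingSequence
    variants: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.variants)

    def mutant_nucleotides(self, i: int) -> str:
        seq = list(self.reference.nucleotides)
        for pos, ref, alt in self.variants[i].nt_substitutions:
            assert seq[pos - 1] == ref
            seq[pos - 1] = alt
        return "".join(seq)

    @property
    def activity_probs(self) -> np.ndarray:
        return np.array([v.true_activity_prob for v in self.variants], dtype=float)

    @property
    def active_mask(self) -> np.ndarray:
        return np.array([bool(v.is_active) for v in self.variants])

    def truth_table(self):
        """Per-variant ground truth as a pandas DataFrame (TSV-friendly)."""
        import pandas as pd

        rows = []
        for v in self.variants:
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "nt_substitutions": ";".join(
                        f"{r}{p}{a}" for p, r, a in v.nt_substitutions
                    ),
                    "aa_substitutions": ";".join(
                        substitution_key(p, r, a) for p, r, a in v.aa_substitutions
                    ),
                    "p_active": v.true_activity_prob,
                    "is_active": v.is_active,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreenConfig:
    """Physical parameters of the simulated droplet sorter.

    Defaults reproduce the screen's reported operating point: ~10% droplet
    occupancy (``lambda = -ln 0.9``), ~3 min on-chip incubation, and gate and
    noise levels under which a 25%-active library sorts to a 60-90% active
    pool. Fluorescence is in arbitrary units (AFU); rates are AFU/min.
    """

    occupancy_lambda: float = -math.log(0.9)
    incubation_min: float = 3.0
    gate_threshold: float = 70.0
    active_rate_mean: float = 100.0
    inactive_rate_mean: float = 10.0
    expression_noise_cv: float = 0.3
    autofluorescence_sd: float = 30.0
    prior_pi: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occupancy_lambda <= 0:
            raise ValueError("occupancy_lambda must be > 0")
        if not 0 < self.prior_pi < 1:
            raise ValueError("prior_pi must lie in (0, 1)")
        for name in ("active_rate_mean", "inactive_rate_mean", "incubation_min",
                     "expression_noise_cv", "autofluorescence_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class VariantPool:
    """A multiset of library variants (cells), stored as library indices."""

    library: VariantLibrary
    indices: np.ndarray
    label: str  # "input" or "sorted"

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def active_fraction(self) -> float:
        if len(self.indices) == 0:
            return float("nan")
        return float(self.library.active_mask[self.indices].mean())


@dataclass
class SortSummary:
    n_droplets: int
    occupied_fraction: float
    n_sorted_droplets: int
    sorted_purity: float
    input_active_fraction: float
    fold_enrichment: float


@dataclass
class ReadSet:
    """Reads from one pool, with per-base Phred qualities."""

    pool: str
    replicate: int
    bases: list[str]
    qualities: list[np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b, q in zip(self.bases, self.qualities):
            if len(b) != len(q):
                raise ValueError("read base and quality strings differ in length")

    def __len__(self) -> int:
        return len(self.bases)

    def mean_qualities(self) -> np.ndarray:
        return np.array([float(np.mean(q)) if len(q) else 0.0 for q in self.qualities])

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i, (b, q) in enumerate(zip(self.bases, self.qualities)):
                qual = "".join(chr(int(x) + 33) for x in q)
                fh.write(f"@{self.pool}_rep{self.replicate}_read{i}\n{b}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path, pool: str, replicate: int) -> "ReadSet":
        from Bio import SeqIO

        bases, quals = [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            bases.append(str(rec.seq))
            quals.append(np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16))
        return cls(pool=pool, replicate=replicate, bases=bases, qualities=quals,
                   provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# library generation


def random_coding_sequence(n_codons: int, seed: int = 0, id: str = "gene",
                           numbering_offset: int = 0) -> CodingSequence:
    """A random internal-stop-free coding sequence (ATG start), for demos
    and tests."""
    rng = np.random.default_rng(seed)
    while True:
        nt = "ATG" + "".join(rng.choice(list(_BASE_STR), size=(n_codons - 1) * 3))
        try:
            return CodingSequence(id=id, nucleotides=nt,
                                  numbering_offset=numbering_offset)
        except ValueError:
            continue


def _codon_table() -> dict[str, str]:
    table = {}
    for a in _BASE_STR:
        for b in _BASE_STR:
            for c in _BASE_STR:
                codon = a + b + c
                table[codon] = translate_codons(codon)
    return table


_CODONS = _codon_table()


def simulate_epcr_library(
    reference: CodingSequence,
    n_variants: int,
    mean_nt_mutations: float = 4.5,
    seed: int = 0,
) -> VariantLibrary:
    """Simulate an error-prone PCR mutant library.

    Each variant carries ``Poisson(mean_nt_mutations)`` single-base
    substitutions at uniformly chosen distinct positions, with the alternative
    base uniform over the three non-reference bases. Amino-acid substitutions
    are derived by codon-wise translation against the reference; positions are
    reported in canonical numbering.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if mean_nt_mutations < 0:
        raise ValueError("mean_nt_mutations must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(reference)
    ref_nt = reference.nucleotides
    counts = rng.poisson(mean_nt_mutations, size=n_variants)
    variants = []
    for i, k in enumerate(counts):
        k = int(min(k, L))
        nt_subs = []
        aa_subs = {}
        if k > 0:
            positions = rng.choice(L, size=k, replace=False)
            positions.sort()
            mutated = {}
            for pos0 in positions:
                ref_base = ref_nt[pos0]
                alts = [b for b in _BASE_STR if b != ref_base]
                alt = alts[rng.integers(0, 3)]
                nt_subs.append((int(pos0) + 1, ref_base, alt))
                mutated[int(pos0)] = alt
            touched_codons = sorted({p // 3 for p in mutated})
            for ci in touched_codons:
                codon = list(ref_nt[ci * 3 : ci * 3 + 3])
                for off in range(3):
                    if ci * 3 + off in mutated:
                        codon[off] = mutated[ci * 3 + off]
                aa_ref = _CODONS[ref_nt[ci * 3 : ci * 3 + 3]]
                aa_alt = _CODONS["".join(codon)]
                if aa_alt != aa_ref:
                    pos = reference.canonical(ci + 1)
                    aa_subs[pos] = (pos, aa_ref, aa_alt)
        variants.append(
            VariantRecord(
                variant_id=f"v{i:06d}",
                nt_substitutions=tuple(nt_subs),
                aa_substitutions=tuple(aa_subs[p] for p in sorted(aa_subs)),
            )
        )
    return VariantLibrary(reference=reference, variants=variants)


# ---------------------------------------------------------------------------
# ground truth


def assign_ground_truth(
    library: VariantLibrary,
    coefficients: Mapping[SubKey, float],
    target_pi: float = 0.25,
    seed: int = 0,
) -> VariantLibrary:
    """Assign latent activity from per-substitution fitness coefficients.

    ``p(active) = logistic(beta0 + sum of coefficients over the variant's
    substitutions)``; any stop-gain substitution forces ``p = 0``. The
    intercept ``beta0`` is solved numerically so the library-mean activity
    probability equals ``target_pi``.
    """
    if not 0 < target_pi < 1:
        raise ValueError("target_pi must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    scores = np.zeros(len(library))
    stop = np.zeros(len(library), dtype=bool)
    for i, v in enumerate(library.variants):
        stop[i] = v.has_stop_gain
        scores[i] = sum(coefficients.get(s, 0.0) for s in v.aa_substitutions)
    viable = ~stop
    max_mean = viable.mean()
    if max_mean <= target_pi:
        raise ValueError(
            f"cannot calibrate intercept: only {max_mean:.1%} of the library is "
            f"free of stop codons, below the target active fraction {target_pi:.1%}"
        )

    def mean_p(beta0: float) -> float:
        p = expit(beta0 + scores)
        p[stop] = 0.0
        return float(p.mean()) - target_pi

    lo, hi = -50.0, 50.0
    beta0 = brentq(mean_p, lo, hi, xtol=1e-12)
    p = expit(beta0 + scores)
    p[stop] = 0.0
    active = rng.random(len(library)) < p
    new = [
        replace(v, true_activity_prob=float(p[i]), is_active=bool(active[i]))
        for i, v in enumerate(library.variants)
    ]
    out = VariantLibrary(reference=library.reference, variants=new)
    out.intercept = float(beta0)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# droplet sorting


def simulate_droplet_sort(
    library: VariantLibrary,
    config: ScreenConfig,
    n_droplets: int = 100_000,
) -> tuple[VariantPool, VariantPool, SortSummary]:
    """Simulate Poisson encapsulation, incubation, and a fluorescence gate.

    Droplets receive ``Poisson(lambda)`` cells; each cell's variant is drawn
    uniformly from the library. Droplet fluorescence is the sum over resident
    cells of ``rate * incubation * lognormal(expression noise)`` plus Gaussian
    autofluorescence. Droplets above the gate contribute *all* resident cells
    to the sorted pool, so co-encapsulated inactive variants hitchhike — the
    dominant false-positive mechanism. The input pool is an unsorted draw of
    comparable size.
    """
    if any(v.is_active is None for v in library.variants):
        raise ValueError("library has no ground truth; call assign_ground_truth first")
    rng = np.random.default_rng(config.seed)
    lam = config.occupancy_lambda
    counts = rng.poisson(lam, size=n_droplets)
    total_cells = int(counts.sum())
    cell_variant = rng.integers(0, len(library), size=total_cells)
    droplet_of_cell = np.repeat(np.arange(n_droplets), counts)

    active = library.active_mask[cell_variant]
    rates = np.where(active, config.active_rate_mean, config.inactive_rate_mean)
    cv = config.expression_noise_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        expr = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=total_cells)
    else:
        expr = np.ones(total_cells)
    signal = rates * config.incubation_min * expr
    fluor = np.bincount(droplet_of_cell, weights=signal, minlength=n_droplets)
    fluor = fluor + rng.normal(0.0, config.autofluorescence_sd, size=n_droplets)

    gated = fluor > config.gate_threshold
    sorted_idx = cell_variant[gated[droplet_of_cell]]
    input_size = max(len(sorted_idx), 1)
    input_idx = rng.integers(0, len(library), size=input_size)

    sorted_pool = VariantPool(library, sorted_idx, "sorted")
    input_pool = VariantPool(library, input_idx, "input")
    purity = sorted_pool.active_fraction
    input_frac = input_pool.active_fraction
    summary = SortSummary(
        n_droplets=n_droplets,
        occupied_fraction=float((counts > 0).mean()),
        n_sorted_droplets=int(gated.sum()),
        sorted_purity=purity,
        input_active_fraction=input_frac,
        fold_enrichment=purity / input_frac if input_frac > 0 else float("inf"),
    )
    return input_pool, sorted_pool, summary


# ---------------------------------------------------------------------------
# sequencing reads


def generate_reads(
    pool: VariantPool,
    depth: int,
    error_rate: float = 0.001,
    seed: int = 0,
    replicate: int = 1,
) -> ReadSet:
    """Sample full-length reads from a pool with i.i.d. per-base errors.

    Phred qualities are constant at ``round(-10 log10(error_rate))`` (capped
    at 40), consistent with the simulated error process.
    """
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must lie in [0, 0.1)")
    if len(pool) == 0:
        raise ValueError("cannot generate reads from an empty pool")
    rng = np.random.default_rng(seed)
    chosen = pool.indices[rng.integers(0, len(pool), size=depth)]
    L = len(pool.library.reference)
    q = 40 if error_rate == 0 else min(40, int(round(-10 * math.log10(error_rate))))
    qual = np.full(L, q, dtype=np.int16)

    cache: dict[int, np.ndarray] = {}
    bases_out: list[str] = []
    quals_out: list[np.ndarray] = []
    for vi in chosen:
        vi = int(vi)
        if vi not in cache:
            cache[vi] = np.frombuffer(
                pool.library.mutant_nucleotides(vi).encode(), dtype="S1"
            )
        read = cache[vi]
        if error_rate > 0:
            mask = rng.random(L) < error_rate
            n_err = int(mask.sum())
            if n_err:
                read = read.copy()
                # shift by 1-3 positions in base order: always a different base
                cur = np.searchsorted(_BASES, read[mask])
                read[mask] = _BASES[(cur + rng.integers(1, 4, size=n_err)) % 4]
        bases_out.append(read.tobytes().decode())
        quals_out.append(qual)
    prov = {"pool": pool.label, "depth": depth, "error_rate": error_rate, "seed": seed}
    return ReadSet(pool=pool.label, replicate=replicate, bases=bases_out,
                   qualities=quals_out, provenance=prov)


# ---------------------------------------------------------------------------
# throughput arithmetic


def expected_throughput(droplet_rate_hz: float, occupancy: float) -> tuple[float, float]:
    """Cells analyzed per second and variants screened per hour.

    At 1000 Hz droplet generation and 10% occupancy the sorter analyzes
    100 cells/s, i.e. 360,000 variants/hour.
    """
    if droplet_rate_hz < 0:
        raise ValueError("droplet rate must be >= 0")
    if not 0 <= occupancy <= 1:
        raise ValueError("occupancy must lie in [0, 1]")
    cells_per_second = droplet_rate_hz * occupancy
    return cells_per_second, 3600.0 * cells_per_second


# ---------------------------------------------------------------------------
# direct PU observation sampler (feature space, no sequencing)


def simulate_pu_observations(
    beta: np.ndarray,
    n_variants: int,
    n_reads_per_pool: int,
    target_pi: float = 0.25,
    subs_per_variant: tuple[int, int] = (2, 4),
    seed: int = 0,
):
    """Sample read-level positive/unlabeled observations from known slopes.

    Builds a variant population where each variant carries a uniform 2-4
    substitutions drawn from ``len(beta)`` features, calibrates the intercept
    to ``target_pi``, then samples the input pool uniformly over variants and
    the sorted pool proportionally to activity probability. Returns
    ``(X, z, beta0)`` with X a CSR indicator matrix over reads (sorted block
    first) and z the pool indicator.
    """
    from scipy import sparse

    rng = np.random.default_rng(seed)
    p = len(beta)
    k = rng.integers(subs_per_variant[0], subs_per_variant[1] + 1, size=n_variants)
    k = np.minimum(k, p)
    rows, cols = [], []
    for i in range(n_variants):
        feats = rng.choice(p, size=int(k[i]), replace=False)
        rows.extend([i] * len(feats))
        cols.extend(feats.tolist())
    V = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_variants, p)
    )
    scores = V @ np.asarray(beta, dtype=float)

    def mean_p(b0):
        return float(expit(b0 + scores).mean()) - target_pi

    beta0 = brentq(mean_p, -50, 50, xtol=1e-12)
    pact = expit(beta0 + scores)

    input_variants = rng.integers(0, n_variants, size=n_reads_per_pool)
    w = pact / pact.sum()
    sorted_variants = rng.choice(n_variants, size=n_reads_per_pool, p=w)
    X = sparse.vstack([V[sorted_variants], V[input_variants]]).tocsr()
    z = np.concatenate(
        [np.ones(n_reads_per_pool, dtype=int), np.zeros(n_reads_per_pool, dtype=int)]
    )
    return X, z, float(beta0)


def provenance_json(config: ScreenConfig) -> str:
    return json.dumps({k: getattr(config, k) for k in config.__dataclass_fields__},
                      sort_keys=True)
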
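"""Per-site mutational tolerance and cross-paralog divergence profiles.

The tolerance of a site is the mean absolute value of the fitness
coefficients of all retained substitutions at that site, reported as a
percentile rank across sites: low percentiles mark functionally critical,
mutation-intolerant positions (active-site residues, zymogen maturation
sites); high percentiles mark permissive surface positions.

Divergence between two paralogs is the site-wise difference of their mean
absolute coefficients on a pairwise-alignment position map, smoothed with a
centered moving average. A conservation-based tolerance profile can also be
computed from a family multiple sequence alignment via normalized column
entropy, for comparison with the screen-derived profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

from .pu import CoefficientTable


@dataclass
class ToleranceProfile:
    """Per-position tolerance scores; ``df`` indexed by canonical position
    with columns ``mean_abs_coefficient``, ``n_mutations``, and (after
    ranking) ``percentile_rank``."""

    df: pd.DataFrame
    source: str = "dms"

    def __post_init__(self) -> None:
        if not self.df.index.is_monotonic_increasing:
            self.df = self.df.sort_index()
        if (self.df["mean_abs_coefficient"] < 0).any():
            raise ValueError("mean absolute coefficients must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df.index.to_numpy()

    def to_tsv(self, path) -> None:
        self.df.reset_index().to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")


@dataclass
class PositionMap:
    """Matched-position pairs from a global pairwise alignment."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a = [p for p, _ in self.pairs]
        b = [q for _, q in self.pairs]
        if sorted(a) != a or sorted(b) != b:
            raise ValueError("position map must be strictly monotone")

    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DivergenceProfile:
    """Aligned-site differences A - B with a moving-average smooth.

    Positive values mark sites where paralog A carries the larger mean
    absolute coefficient (mutations matter more in A)."""

    df: pd.DataFrame  # index: position in A; columns: position_b, delta, smoothed_delta
    window: int


def site_tolerance(coefficients: CoefficientTable, source: str = "dms") -> ToleranceProfile:
    """Mean |beta| over all retained substitutions at each position.

    Positions with no retained substitutions are absent, not zero-filled:
    "no data" and "perfectly intolerant" must stay distinguishable.
    """
    if len(coefficients) == 0:
        raise ValueError("coefficient table is empty")
    absbeta = coefficients.df["beta"].abs()
    grouped = absbeta.groupby(level="position")
    df = pd.DataFrame(
        {
            "mean_abs_coefficient": grouped.mean(),
            "n_mutations": grouped.size().astype(int),
        }
    )
    df.index.name = "position"
    return ToleranceProfile(df=df, source=source)


def percentile_rank(profile: ToleranceProfile) -> ToleranceProfile:
    """Attach percentile ranks ``rank / n * 100`` (average rank at ties)."""
    if len(profile) < 2:
        raise ValueError("need at least 2 positions to rank")
    vals = profile.df["mean_abs_coefficient"].to_numpy()
    ranks = rankdata(vals, method="average") / len(vals) * 100.0
    df = profile.df.copy()
    df["percentile_rank"] = ranks
    return ToleranceProfile(df=df, source=profile.source)


def align_positions(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
    offset_a: int = 0,
    offset_b: int = 0,
) -> PositionMap:
    """Global pairwise protein alignment reduced to matched-position pairs.

    Offsets convert 1-based sequence positions to canonical numbering.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for k in range(a_end - a_start):
            pairs.append((a_start + k + 1 + offset_a, b_start + k + 1 + offset_b))
    return PositionMap(pairs=pairs)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window truncated at the edges."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def divergence_profile(
    profile_a: ToleranceProfile,
    profile_b: ToleranceProfile,
    position_map: PositionMap,
    window: int = 9,
) -> DivergenceProfile:
    """Site-wise tolerance difference A - B on aligned positions, smoothed.

    Only aligned positions scored in both profiles contribute. The smooth is
    a centered moving average of width ``window`` (odd), truncated at edges.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    a_tol = profile_a.df["mean_abs_coefficient"]
    b_tol = profile_b.df["mean_abs_coefficient"]
    rows = []
    for pa, pb in position_map.pairs:
        if pa in a_tol.index and pb in b_tol.index:
            rows.append((pa, pb, float(a_tol[pa] - b_tol[pb])))
    if len(rows) < window:
        raise ValueError(
            f"only {len(rows)} aligned scored positions; need >= window ({window})"
        )
    df = pd.DataFrame(rows, columns=["position_a", "position_b", "delta"])
    df = df.set_index("position_a")
    df["smoothed_delta"] = moving_average(df["delta"].to_numpy(), window)
    return DivergenceProfile(df=df, window=window)


def msa_tolerance(
    msa_path_or_alignment,
    reference_row: str,
    max_gap_fraction: float = 0.5,
) -> ToleranceProfile:
    """Conservation-based tolerance from a family MSA.

    Per reference (non-gap) column, the score is the Shannon entropy of the
    residue composition (gaps excluded) normalized by ``log(20)``; perfectly
    conserved columns score 0 (least tolerant). Columns with more than
    ``max_gap_fraction`` gaps are omitted. Ranks are attached by
    :func:`percentile_rank` downstream.
    """
    if isinstance(msa_path_or_alignment, (str, bytes)) or hasattr(msa_path_or_alignment, "__fspath__"):
        aln = AlignIO.read(str(msa_path_or_alignment), "fasta")
    else:
        aln = msa_path_or_alignment
    if len(aln) < 5:
        raise ValueError("need at least 5 sequences in the MSA")
    ref = None
    for rec in aln:
        if rec.id == reference_row:
            ref = str(rec.seq)
            break
    if ref is None:
        raise ValueError(f"reference row {reference_row!r} not found in MSA")
    n_seq = len(aln)
    cols = np.array([list(str(r.seq)) for r in aln])
    rows = []
    ref_pos = 0
    for ci, ref_char in enumerate(ref):
        if ref_char in "-.":
            continue
        ref_pos += 1
        col = cols[:, ci]
        residues = col[(col != "-") & (col != ".")]
        gap_frac = 1.0 - len(residues) / n_seq
        if gap_frac > max_gap_fraction:
            continue
        _, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        entropy = float(-(freqs * np.log(freqs)).sum())
        rows.append((ref_pos, entropy / np.log(20.0), len(residues)))
    df = pd.DataFrame(rows, columns=["position", "mean_abs_coefficient", "n_mutations"])
    df = df.set_index("position")
    return ToleranceProfile(df=df, source="msa")


def coefficient_difference_matrix(
    coef_a: CoefficientTable,
    coef_b: CoefficientTable,
    position_map: PositionMap,
) -> pd.DataFrame:
    """``beta_A - beta_B`` per (aligned position, alt residue).

    A cell exists only where the same alternative residue is scored in both
    paralogs at aligned positions; missing-in-either stays NaN (absent), not
    zero. Rows are indexed by position in A; the reference residues may
    differ between paralogs and are not part of the key.
    """
    if len(coef_a) == 0 or len(coef_b) == 0:
        raise ValueError("coefficient tables must be non-empty")
    a = coef_a.df["beta"]
    b = coef_b.df["beta"]
    b_by_pos_alt: dict[tuple[int, str], float] = {}
    for (pos, _ref, alt), val in b.items():
        b_by_pos_alt[(pos, alt)] = float(val)
    ab = position_map.a_to_b()
    cells: dict[tuple[int, str], float] = {}
    for (pos, _ref, alt), val in a.items():
        pb = ab.get(pos)
        if pb is None:
            continue
        other = b_by_pos_alt.get((pb, alt))
        if other is not None:
            cells[(pos, alt)] = float(val) - other
    if not cells:
        idx = pd.MultiIndex.from_arrays([[], []], names=["position", "alt"])
        return pd.DataFrame({"delta_beta": []}, index=idx)
    idx = pd.MultiIndex.from_tuples(sorted(cells), names=["position", "alt"])
    return pd.DataFrame(
        {"delta_beta": [cells[k] for k in sorted(cells)]}, index=idx
    ).unstack("alt")["delta_beta"]


def site_divergence_significance(
    coef_a: CoefficientTable,
    coef_b: CoefficientTable,
    position_map: PositionMap,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test for per-site tolerance differences between paralogs.

    At each aligned site the observed statistic is the difference of mean
    |beta| between A and B. Substitution-level |beta| values are pooled and
    reassigned to the two enzymes at random within the site to build the
    null; two-sided p-values are Benjamini-Hochberg corrected.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    a_abs = coef_a.df["beta"].abs().groupby(level="position")
    b_abs = coef_b.df["beta"].abs().groupby(level="position")
    a_groups = {p: g.to_numpy() for p, g in a_abs}
    b_groups = {p: g.to_numpy() for p, g in b_abs}
    rows = []
    for pa, pb in position_map.pairs:
        xa = a_groups.get(pa)
        xb = b_groups.get(pb)
        if xa is None or xb is None:
            continue
        obs = xa.mean() - xb.mean()
        pooled = np.concatenate([xa, xb])
        na = len(xa)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(pooled)
            null[i] = perm[:na].mean() - perm[na:].mean()
        pval = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_permutations + 1.0)
        rows.append((pa, pb, obs, pval))
    df = pd.DataFrame(rows, columns=["position_a", "position_b", "delta", "pvalue"])
    if len(df):
        rej, qvals, _, _ = multipletests(df["pvalue"], alpha=alpha, method="fdr_bh")
        df["qvalue"] = qvals
        df["significant"] = rej
    return df.set_index("position_a")
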
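"""End-to-end screen pipeline: simulate/load -> QC -> call -> count ->
threshold -> PU fit -> replicate concordance -> tolerance and divergence
profiles, with a run manifest recording config, seeds, and outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calling import (apply_count_threshold, build_count_table, call_reads,
                      filter_reads_by_quality)
from .config import Config, load_config
from .profiles import (ToleranceProfile, align_positions, divergence_profile,
                       percentile_rank, site_tolerance)
from .pu import (FeatureMatrix, PULogisticModel, combine_replicates,
                 replicate_concordance)
from .sequences import CodingSequence
from .synth import (ScreenConfig, assign_ground_truth, generate_reads,
                    random_coding_sequence, simulate_droplet_sort,
                    simulate_epcr_library)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    excluded_replicates: dict[str, list[int]] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _stage_seed(base: int, *tags: int) -> int:
    """Deterministic per-stage seed below 2^31 derived from the run seed."""
    ss = np.random.SeedSequence([int(base), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _random_reference(n_codons: int, seed: int, gene_id: str,
                      offset: int) -> CodingSequence:
    return random_coding_sequence(n_codons, seed=seed, id=gene_id,
                                  numbering_offset=offset)


def _simulate_truth_coefficients(library, sd: float, seed: int) -> dict:
    """Random true coefficients, one per substitution seen in the library."""
    rng = np.random.default_rng(seed)
    keys = sorted({s for v in library.variants for s in v.aa_substitutions})
    return {k: float(rng.normal(0.0, sd)) for k in keys}


def run_screen_pipeline(config_path_or_cfg, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full pipeline described by a config file.

    With ``simulate: true`` the synthetic screen supplies reads; otherwise
    FASTQ inputs are expected next to the reference (one pair per replicate,
    named ``<gene>_rep<r>_{input,sorted}.fastq`` in ``out_dir``'s input
    folder — pre-aligned full-length reads only). Writes per-replicate
    coefficient TSVs, combined coefficients, tolerance profiles, an optional
    two-gene divergence profile, and ``manifest.json``.
    """
    cfg: Config = config_path_or_cfg if isinstance(config_path_or_cfg, Config) \
        else load_config(config_path_or_cfg)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.dump(), seed=cfg.seed)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dropdms")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest.outputs["log"] = str(log_path)

    try:
        _run(cfg, out, manifest)
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def _run(cfg: Config, out: Path, manifest: RunManifest) -> None:
    # --- references -------------------------------------------------------
    try:
        if cfg.reference_fasta:
            refs = CodingSequence.all_from_fasta(
                cfg.reference_fasta, numbering_offset=cfg.library.numbering_offset
            )
            manifest.input_digests[cfg.reference_fasta] = _digest(Path(cfg.reference_fasta))
        elif cfg.simulate:
            s = _stage_seed(cfg.seed, 0)
            refs = [_random_reference(cfg.library.gene_codons, s, "geneA",
                                      cfg.library.numbering_offset)]
            manifest.stage_seeds["reference"] = s
        else:
            raise ValueError("reference_fasta is required when simulate is false")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reference", exc) from exc

    combined_tables = {}
    profiles: dict[str, ToleranceProfile] = {}
    for gi, ref in enumerate(refs):
        combined_tables[ref.id], profiles[ref.id] = _run_gene(cfg, out, manifest, ref, gi)

    # --- divergence between two genes -------------------------------------
    if len(refs) == 2:
        try:
            a, b = refs
            pmap = align_positions(
                a.protein.rstrip("*"), b.protein.rstrip("*"),
                offset_a=a.numbering_offset, offset_b=b.numbering_offset,
            )
            div = divergence_profile(profiles[a.id], profiles[b.id], pmap,
                                     window=cfg.profiles.window)
            path = out / f"divergence_{a.id}_vs_{b.id}.tsv"
            div.df.reset_index().to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")
            manifest.outputs["divergence"] = str(path)
        except Exception as exc:
            raise StageError("divergence", exc) from exc


def _run_gene(cfg: Config, out: Path, manifest: RunManifest,
              ref: CodingSequence, gi: int):
    gene = ref.id
    n_reps = cfg.sequencing.n_replicates

    # --- simulate or load reads -------------------------------------------
    readsets = []  # (replicate, input ReadSet, sorted ReadSet)
    if cfg.simulate:
        try:
            lib_seed = _stage_seed(cfg.seed, 1, gi)
            library = simulate_epcr_library(
                ref, cfg.library.n_variants, cfg.library.mean_nt_mutations,
                seed=lib_seed,
            )
            truth_seed = _stage_seed(cfg.seed, 2, gi)
            truth = _simulate_truth_coefficients(
                library, cfg.library.truth_beta_sd, truth_seed
            )
            library = assign_ground_truth(library, truth,
                                          target_pi=cfg.screen.prior_pi,
                                          seed=_stage_seed(cfg.seed, 3, gi))
            manifest.stage_seeds[f"{gene}.library"] = lib_seed
            manifest.stage_seeds[f"{gene}.truth"] = truth_seed
            tt = library.truth_table()
            tt.to_csv(out / f"{gene}_truth.tsv", sep="\t", index=False)
            manifest.outputs[f"{gene}.truth"] = str(out / f"{gene}_truth.tsv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("simulate_library", exc) from exc

        for r in range(1, n_reps + 1):
            try:
                rep_library = library
                if r in cfg.library.shuffled_replicates:
                    # permute latent labels: this replicate's sorted pool is
                    # uninformative, as a constructed QC outlier
                    import dataclasses
                    rng = np.random.default_rng(_stage_seed(cfg.seed, 9, gi, r))
                    perm = rng.permutation(len(library))
                    active = library.active_mask[perm]
                    probs = library.activity_probs[perm]
                    rep_library = type(library)(
                        reference=library.reference,
                        variants=[
                            dataclasses.replace(v, is_active=bool(active[i]),
                                                true_activity_prob=float(probs[i]))
                            for i, v in enumerate(library.variants)
                        ],
                    )
                sort_seed = _stage_seed(cfg.seed, 4, gi, r)
                screen = ScreenConfig(
                    occupancy_lambda=cfg.screen.occupancy_lambda,
                    incubation_min=cfg.screen.incubation_min,
                    gate_threshold=cfg.screen.gate_threshold,
                    active_rate_mean=cfg.screen.active_rate_mean,
                    inactive_rate_mean=cfg.screen.inactive_rate_mean,
                    expression_noise_cv=cfg.screen.expression_noise_cv,
                    autofluorescence_sd=cfg.screen.autofluorescence_sd,
                    prior_pi=cfg.screen.prior_pi,
                    seed=sort_seed,
                )
                inp, srt, summary = simulate_droplet_sort(
                    rep_library, screen, n_droplets=cfg.screen.n_droplets
                )
                manifest.stage_counts[f"{gene}.rep{r}.sort"] = summary.__dict__
                in_reads = generate_reads(inp, cfg.sequencing.depth,
                                          cfg.sequencing.error_rate,
                                          seed=_stage_seed(cfg.seed, 5, gi, r),
                                          replicate=r)
                so_reads = generate_reads(srt, cfg.sequencing.depth,
                                          cfg.sequencing.error_rate,
                                          seed=_stage_seed(cfg.seed, 6, gi, r),
                                          replicate=r)
                for rs, tag in ((in_reads, "input"), (so_reads, "sorted")):
                    p = out / f"{gene}_rep{r}_{tag}.fastq"
                    rs.to_fastq(p)
                    manifest.outputs[f"{gene}.rep{r}.{tag}.fastq"] = str(p)
                readsets.append((r, in_reads, so_reads))
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"simulate_screen_rep{r}", exc) from exc
    else:
        from .synth import ReadSet

        for r in range(1, n_reps + 1):
            try:
                base = Path(cfg.reference_fasta).parent
                inp = ReadSet.from_fastq(base / f"{gene}_rep{r}_input.fastq", "input", r)
                srt = ReadSet.from_fastq(base / f"{gene}_rep{r}_sorted.fastq", "sorted", r)
                readsets.append((r, inp, srt))
            except Exception as exc:
                raise StageError(f"load_reads_rep{r}", exc) from exc

    # --- QC, calling, counting, PU fit per replicate ----------------------
    rep_tables = []
    for r, in_reads, so_reads in readsets:
        try:
            in_q = filter_reads_by_quality(in_reads, cfg.pipeline.min_read_quality)
            so_q = filter_reads_by_quality(so_reads, cfg.pipeline.min_read_quality)
            table = build_count_table(in_q, so_q, ref, replicate=r)
            table = apply_count_threshold(table, cfg.pipeline.min_mutation_count)
            if len(table) == 0:
                raise ValueError("no substitutions survive the count threshold")
            in_calls = call_reads(in_q, ref)
            so_calls = call_reads(so_q, ref)
            fm = FeatureMatrix.from_read_calls(in_calls, so_calls,
                                               table.substitutions)
            model = PULogisticModel(fm, prior_pi=cfg.screen.prior_pi)
            res = model.fit(l2_penalty=cfg.fit.l2_penalty, tol=cfg.fit.tol,
                            max_iter=cfg.fit.max_iter, compute_se=False)
            ct = res.coefficient_table()
            path = out / f"{gene}_rep{r}_coefficients.tsv"
            ct.to_tsv(path)
            manifest.outputs[f"{gene}.rep{r}.coefficients"] = str(path)
            manifest.stage_counts[f"{gene}.rep{r}.fit"] = {
                "n_reads_input": table.totals.get("input"),
                "n_reads_sorted": table.totals.get("sorted"),
                "n_substitutions": len(table),
                "converged": res.converged,
            }
            rep_tables.append(ct)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"fit_rep{r}", exc) from exc

    # --- concordance, combination, tolerance profile -----------------------
    try:
        excluded: list[int] = []
        if len(rep_tables) >= 2:
            corr, excluded = replicate_concordance(
                rep_tables, exclusion_threshold=cfg.fit.exclusion_threshold
            )
            corr.to_csv(out / f"{gene}_replicate_correlations.tsv", sep="\t")
            manifest.outputs[f"{gene}.replicate_correlations"] = str(
                out / f"{gene}_replicate_correlations.tsv")
        manifest.excluded_replicates[gene] = excluded
        combined = combine_replicates(rep_tables, excluded)
        cpath = out / f"{gene}_coefficients.tsv"
        combined.to_tsv(cpath)
        manifest.outputs[f"{gene}.coefficients"] = str(cpath)
        profile = percentile_rank(site_tolerance(combined))
        ppath = out / f"{gene}_tolerance.tsv"
        profile.to_tsv(ppath)
        manifest.outputs[f"{gene}.tolerance"] = str(ppath)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("profiles", exc) from exc
    return combined, profile
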
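"""End-to-end orchestration: configuration, seeding, standard outputs.

A run reads a training alignment (and optionally a strain panel and a codon
FASTA), fits the Potts and independent models, and writes the per-site
entropy profile, polymorphism confrontation, epistasis tables and neutral
simulation, together with a machine-readable JSON summary. One global seed
fans out deterministically to per-stage seeds via SHA-256 of
``"<seed>:<stage>"`` (first four bytes, mod 2³¹), so stages are isolated
but the whole run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from dcaland import __version__
from dcaland.entropy import classify_sites, site_profiles
from dcaland.models import save_model
from dcaland.msa import compute_weights, filter_training_sequences, mask_gappy_columns, read_msa
from dcaland.plm import PlmConfig, fit_ind, fit_plm
from dcaland.polymorphism import (
    allele_frequencies,
    classify_site_status,
    native_rank_profile,
    sample_null_mutations,
    score_observed_polymorphisms,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Named, documented per-stage seed derivation (stable across runs)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All thresholds of the pipeline, with the study defaults."""

    training_msa: str = ""
    panel_msa: str | None = None
    codon_fasta: str | None = None
    reference_id: str = ""
    output_dir: str = "dcaland_out"
    theta: float = 0.2
    lambda_h: float = 0.01
    lambda_J: float = 0.01
    max_column_gap_frac: float = 0.2
    max_seq_gap_frac: float = 0.1
    max_ref_identity: float = 0.9
    min_sequences: int = 200
    polymorphism_threshold: float = 0.05
    entropy_threshold_bits: float = 1.0
    contact_cutoff: float = 10.0
    observed_synonymous_stat: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key = value file (one pair per line, '#' comments)."""
        kwargs = {}
        fields = {f for f in cls.__dataclass_fields__}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            hint = str(cls.__dataclass_fields__[key].type)
            if value.lower() in ("none", ""):
                kwargs[key] = None
            elif "float" in hint:
                kwargs[key] = float(value)
            elif "int" in hint:
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _tsv_header(config: RunConfig) -> str:
    return (
        f"# dcaland {__version__} | config_hash={config.config_hash()} | seed={config.seed}\n"
    )


def write_table(df, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute fit → entropy → polymorphism (and neutral-sim when a codon
    layer is given); returns the summary dict also written to summary.json."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    try:
        msa = read_msa(config.training_msa, reference_id=config.reference_id)
        projected = msa
        from dcaland.msa import project_to_reference

        projected, cmap = project_to_reference(msa, config.reference_id)
        analyzable = mask_gappy_columns(projected, config.max_column_gap_frac)
        cmap.analyzable = analyzable
        cmap.write_tsv(out / "column_map.tsv")
        training = filter_training_sequences(
            projected,
            max_ref_identity=config.max_ref_identity,
            max_seq_gap_frac=config.max_seq_gap_frac,
            min_sequences=config.min_sequences,
        )
        weights = compute_weights(training, theta=config.theta)
    except Exception as exc:
        raise StageError(f"stage 'prepare' failed: {exc}") from exc

    try:
        plm_config = PlmConfig(
            lambda_h=config.lambda_h,
            lambda_J=config.lambda_J,
            theta=config.theta,
            seed=derive_seed(config.seed, "fit"),
        )
        model = fit_plm(training, weights, plm_config)
        ind = fit_ind(training, weights)
        save_model(model, out / "potts_model.h5")
        save_model(ind, out / "ind_model.h5")
        summary["m_eff"] = weights.m_eff
        summary["n_training_sequences"] = training.M
    except Exception as exc:
        raise StageError(f"stage 'fit' failed: {exc}") from exc

    reference = projected.reference_row()
    sites = [int(s) for s in np.flatnonzero(analyzable) + 1]
    try:
        profile = site_profiles(
            model, ind, reference, sites=sites, entropy_threshold=config.entropy_threshold_bits
        )
        write_table(profile, out / "entropy_profile.tsv", config)
        _, fractions = classify_sites(profile, config.entropy_threshold_bits)
        summary["category_fractions"] = fractions
        summary["median_ig_bits"] = float(profile["ig"].median())
    except Exception as exc:
        raise StageError(f"stage 'entropy' failed: {exc}") from exc

    if config.panel_msa:
        try:
            panel = read_msa(config.panel_msa)
            table = allele_frequencies(panel)
            status = classify_site_status(table, config.polymorphism_threshold)
            write_table(status, out / "site_status.tsv", config)
            ranks_potts = native_rank_profile(model, reference, sites=sites)
            ranks_ind = native_rank_profile(ind, reference, sites=sites)
            obs = score_observed_polymorphisms(
                model, reference, table, config.polymorphism_threshold, sites=sites
            )
            write_table(obs, out / "observed_polymorphism_scores.tsv", config)
            null_scores = sample_null_mutations(
                model,
                ind,
                reference,
                mode="random",
                n=max(len(obs), 100),
                seed=derive_seed(config.seed, "null"),
                sites=sites,
            )
            summary["potts_native_rank1_fraction"] = ranks_potts.attrs["rank1_fraction"]
            summary["ind_native_rank1_fraction"] = ranks_ind.attrs["rank1_fraction"]
            summary["observed_score_median"] = (
                float(obs["delta_e"].median()) if len(obs) else None
            )
            summary["random_score_median"] = float(np.median(null_scores))
            summary["status_counts"] = status["status"].value_counts(dropna=True).to_dict()
        except Exception as exc:
            raise StageError(f"stage 'polymorphism' failed: {exc}") from exc

    if config.codon_fasta:
        try:
            from dcaland.codons import calibration_sites, read_codon_reference
            from dcaland.neutral import NeutralSimConfig, calibrate_lambda, simulate_genome

            codon_ref = read_codon_reference(config.codon_fasta)
            summary["n_calibration_sites"] = len(calibration_sites(codon_ref))
            if config.observed_synonymous_stat is not None:
                sim_config = NeutralSimConfig(seed=derive_seed(config.seed, "neutral"))
                calib = calibrate_lambda(
                    codon_ref, config.observed_synonymous_stat, sim_config
                )
                write_table(calib.to_frame(), out / "neutral_calibration.tsv", config)
                sim = simulate_genome(
                    codon_ref, model, reference, calib.selected_lambda, sim_config, sites=sites
                )
                write_table(sim, out / "neutral_simulation.tsv", config)
                summary["selected_lambda"] = calib.selected_lambda
                summary["simulated_polymorphic_fraction"] = sim.attrs["polymorphic_fraction"]
        except Exception as exc:
            raise StageError(f"stage 'neutral-sim' failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
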
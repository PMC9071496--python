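"""Conservation contrast of PTM positions against sampled backgrounds.

For each protein, the mean per-residue conservation score (phastCons-
style, in [0, 1]) at its PTM positions is compared with the mean over
``background_n`` randomly sampled non-PTM positions of the same protein
(100 by default). The cohort summary reports the fraction of proteins
whose PTM positions are the more conserved, the fraction whose PTM mean
exceeds the high-conservation threshold, and a two-sample
Kolmogorov-Smirnov test of the pooled PTM scores against the pooled
background scores.

Scores are consumed per residue; collapsing nucleotide-level tracks to
residues (e.g. mean over the codon) happens upstream of this module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import derive_seed
from .errors import RbptmError

logger = logging.getLogger(__name__)


class EmptyBackgroundPool(RbptmError):
    pass


@dataclass
class ConservationProfile:
    """Per-residue conservation scores for one protein.

    ``scores`` is a float array of length ``length`` indexed by
    position-1; missing residues are NaN. The background pool defaults
    to every scored residue.
    """

    accession: str
    scores: np.ndarray

    @property
    def scored_positions(self):
        return set((np.flatnonzero(~np.isnan(self.scores)) + 1).tolist())

    def score_at(self, positions):
        idx = np.asarray(sorted(positions), dtype=int) - 1
        return self.scores[idx]


@dataclass
class ProteinContrast:
    accession: str
    ptm_mean: float
    background_mean: float
    more_conserved: bool  # strict: ties count as NOT more conserved
    n_background: int
    ptm_scores: tuple = ()
    background_scores: tuple = ()


@dataclass
class CohortSummary:
    n_proteins: int
    frac_more_conserved: float
    frac_high_conservation: float
    ks_statistic: float
    ks_p: float


def sample_background(profile, n, seed, exclude=frozenset()):
    """Draw n background positions from the protein's scored residues,
    excluding PTM positions.

    Uniform without replacement when the eligible pool holds >= n
    positions; otherwise with replacement (logged). Deterministic for a
    fixed seed.
    """
    pool = sorted(profile.scored_positions - set(exclude))
    if not pool:
        raise EmptyBackgroundPool(f"{profile.accession}: no eligible background positions")
    rng = np.random.default_rng(seed)
    if len(pool) >= n:
        picks = rng.choice(len(pool), size=n, replace=False)
    else:
        logger.info("%s: pool of %d < n=%d, sampling with replacement",
                    profile.accession, len(pool), n)
        picks = rng.choice(len(pool), size=n, replace=True)
    return [pool[i] for i in picks]


def protein_contrast(profile, ptm_positions, config):
    """Contrast one protein's PTM-site scores against its background
    sample. Returns None (with a log entry) when no PTM position has a
    score. The background seed derives from (config.seed, accession) so
    cohort runs are order-independent."""
    scored_ptm = sorted(set(ptm_positions) & profile.scored_positions)
    if not scored_ptm:
        logger.info("%s: no scored PTM positions, skipped", profile.accession)
        return None
    seed = derive_seed(config.seed, "conservation", profile.accession)
    background = sample_background(profile, config.background_n, seed,
                                   exclude=set(ptm_positions))
    ptm_scores = profile.score_at(scored_ptm)
    bg_scores = profile.scores[np.asarray(background, dtype=int) - 1]
    ptm_mean = float(ptm_scores.mean())
    bg_mean = float(bg_scores.mean())
    return ProteinContrast(
        accession=profile.accession,
        ptm_mean=ptm_mean,
        background_mean=bg_mean,
        more_conserved=bool(ptm_mean > bg_mean),
        n_background=len(background),
        ptm_scores=tuple(float(x) for x in ptm_scores),
        background_scores=tuple(float(x) for x in bg_scores),
    )


def cohort_summary(contrasts, config):
    """Aggregate per-protein contrasts over the cohort."""
    contrasts = [c for c in contrasts if c is not None]
    if len(contrasts) < 2:
        raise RbptmError("cohort_summary needs >= 2 protein contrasts")
    pooled_ptm = np.concatenate([np.asarray(c.ptm_scores) for c in contrasts])
    pooled_bg = np.concatenate([np.asarray(c.background_scores) for c in contrasts])
    ks = stats.ks_2samp(pooled_ptm, pooled_bg, method="asymp")
    return CohortSummary(
        n_proteins=len(contrasts),
        frac_more_conserved=float(np.mean([c.more_conserved for c in contrasts])),
        frac_high_conservation=float(
            np.mean([c.ptm_mean > config.high_conservation_threshold for c in contrasts])
        ),
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


# ---------------------------------------------------------------------------
# IO: TSV of (accession, position, score)

def read_conservation(path, proteome):
    """Read a per-residue score table into per-protein profiles; rows on
    unknown accessions or positions beyond the protein are dropped with
    a logged count."""
    frame = pd.read_csv(path, sep="\t", dtype={"accession": str})
    profiles = {}
    dropped = 0
    for accession, group in frame.groupby("accession"):
        protein = proteome.get(accession)
        if protein is None:
            dropped += len(group)
            continue
        scores = np.full(protein.length, np.nan)
        pos = group["position"].to_numpy(dtype=int)
        ok = (pos >= 1) & (pos <= protein.length)
        dropped += int((~ok).sum())
        scores[pos[ok] - 1] = group["score"].to_numpy(dtype=float)[ok]
        profiles[accession] = ConservationProfile(accession, scores)
    if dropped:
        logger.warning("conservation: dropped %d score rows", dropped)
    return profiles


def write_conservation(profiles, path):
    with open(path, "w") as fh:
        fh.write("accession\tposition\tscore\n")
        for accession in sorted(profiles):
            profile = profiles[accession]
            for i, score in enumerate(profile.scores):
                if not np.isnan(score):
                    fh.write(f"{accession}\t{i + 1}\t{score:.6f}\n")
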
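"""Canned study-condition experiments.

These functions freeze the simulation designs used to interrogate the
pipeline's scientific behaviour — protocol-versus-biology clustering,
miR* inversion localisation, size-factor recovery, and the null/power
behaviour of the differential-expression test — so that the test suite and
the reproduction script run exactly the same experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthio
from .align import align_reads
from .annotate import count_mirnas, detection_summary
from .compare import Dendrogram, StarRatioReport, hierarchical_cluster, star_ratio_report
from .quantify import de_test, glog_transform, size_factors
from .synthio import ProtocolProfile, ReferenceBundle, make_truth, simulate_library
from .trim import trim_library, trimmed_sequences

#: The two emulated protocols at full strength: identical biology goes in,
#: protocol-specific composition comes out. Read-through is certain and the
#: background fractions are zero because neither contributes information to
#: the miRNA count matrix these studies analyse.
PROFILE_STANDARD = ProtocolProfile(
    name="illumina_like", modal_length=22, length_sd=1.2, star_enrichment=1.0,
    unannotated_fraction=0.0, adapter=synthio.ILLUMINA_ADAPTER, readthrough_prob=1.0,
)
PROFILE_IDT = ProtocolProfile(
    name="idt_like", modal_length=23, length_sd=1.2, star_enrichment=5.0,
    unannotated_fraction=0.0, adapter=synthio.IDT_ADAPTER, readthrough_prob=1.0,
)

#: Planted biology for the clustering study: a modest cell-type effect on a
#: fifth of the mature species, well below the miR* protocol distortion.
CELL_EFFECT_FOLD = 1.5
CELL_EFFECT_SHARE = 0.2
REPLICATE_SIGMA = 0.2  # lognormal sd of replicate-level abundance jitter


def _count_library(reference, truth, profile, seed, library_id, cache):
    lib = simulate_library(reference, truth, profile, seed=seed,
                           library_id=library_id)
    trimmed, _ = trim_library(lib.reads, profile.adapter)
    records, _ = align_reads(
        list(trimmed_sequences(trimmed)), reference.genome_index(), cache=cache
    )
    return count_mirnas(records, reference.matures), lib


@dataclass
class ClusteringStudyResult:
    fraction_protocol_split: float
    n_replicates: int
    per_replicate: list[bool]
    example_dendrogram: Dendrogram
    example_counts: pd.DataFrame
    fraction_detected_everywhere: float


def protocol_clustering_study(
    seed: int,
    n_replicates: int = 100,
    n_reads: int = 1200,
    n_mirnas: int = 15,
) -> ClusteringStudyResult:
    """Does the dendrogram's top split follow protocol or cell type?

    Eight libraries per replicate — 2 protocol profiles x 2 cell types x 2
    replicates — share one biological baseline per cell type (plus
    replicate-level jitter); the only protocol-level distortion is the
    miR* enrichment of the IDT-like profile. Each replicate runs the full
    trim/align/count/normalise/cluster chain and records whether the top
    split separates the two protocols.
    """
    reference = synthio.make_reference(seed=seed, n_mirnas=n_mirnas)
    matures = sorted(n for n, r in reference.matures.items() if r.arm == "mature")
    effect = {m: CELL_EFFECT_FOLD
              for m in matures[: max(1, int(len(matures) * CELL_EFFECT_SHARE))]}
    cache: dict = {}
    outcomes: list[bool] = []
    example = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 10_000 + rep)
        columns: dict[str, pd.Series] = {}
        for profile in (PROFILE_STANDARD, PROFILE_IDT):
            for cell in ("X", "Y"):
                for repl in range(2):
                    truth = make_truth(
                        reference, n_reads, seed=seed + 20_000 + rep,
                        effect=effect if cell == "Y" else None,
                        replicate_sigma=REPLICATE_SIGMA,
                        replicate_seed=int(rng.integers(2**31)),
                    )
                    lib_id = f"{profile.name}_{cell}_{repl}"
                    counts, _ = _count_library(
                        reference, truth, profile,
                        seed=int(rng.integers(2**31)),
                        library_id=lib_id, cache=cache,
                    )
                    columns[lib_id] = counts
        cm = pd.DataFrame(columns)
        dendro = hierarchical_cluster(glog_transform(cm))
        left, right = dendro.top_split()
        by_protocol = {
            frozenset(c for c in cm.columns if c.startswith(PROFILE_STANDARD.name)),
            frozenset(c for c in cm.columns if c.startswith(PROFILE_IDT.name)),
        }
        outcomes.append({left, right} == by_protocol)
        if example is None:
            example = (dendro, cm)
    dendro, cm = example
    _, frac_detected = detection_summary(cm)
    return ClusteringStudyResult(
        fraction_protocol_split=float(np.mean(outcomes)),
        n_replicates=n_replicates,
        per_replicate=outcomes,
        example_dendrogram=dendro,
        example_counts=cm,
        fraction_detected_everywhere=frac_detected,
    )


@dataclass
class StarStudyResult:
    report: StarRatioReport
    idt_libraries: list[str]
    other_libraries: list[str]

    @property
    def inversions_in_idt(self) -> int:
        return int(self.report.per_library[self.idt_libraries].sum())

    @property
    def inversions_elsewhere(self) -> int:
        return int(self.report.per_library[self.other_libraries].sum())


def star_localisation_study(
    seed: int, n_reads: int = 2000, star_fraction: float = 0.3
) -> StarStudyResult:
    """Plant 5x miR* enrichment in IDT-like libraries only; flag inversions.

    Baseline star abundance is 0.3x the mature partner, so the enriched
    libraries carry star/mature ratios around 1.5 while unenriched ones
    stay near 0.3 — inversions should appear only where the enrichment was
    planted.
    """
    reference = synthio.make_reference(seed=seed)
    truth = make_truth(reference, n_reads, seed=seed + 1,
                       star_fraction=star_fraction)
    cache: dict = {}
    columns: dict[str, pd.Series] = {}
    layout = [
        ("idt_1", PROFILE_IDT), ("idt_2", PROFILE_IDT),
        ("std_1", PROFILE_STANDARD), ("std_2", PROFILE_STANDARD),
    ]
    for i, (lib_id, profile) in enumerate(layout):
        counts, _ = _count_library(reference, truth, profile,
                                   seed=seed + 100 + i,
                                   library_id=lib_id, cache=cache)
        columns[lib_id] = counts
    cm = pd.DataFrame(columns)
    report = star_ratio_report(cm, reference.mirna_pairs())
    return StarStudyResult(
        report=report,
        idt_libraries=["idt_1", "idt_2"],
        other_libraries=["std_1", "std_2"],
    )


def size_factor_recovery_study(
    seed: int, planted=(0.5, 1.0, 2.0, 4.0), n_species: int = 200
) -> float:
    """Max relative error of recovered factor ratios under Poisson noise."""
    rng = np.random.default_rng(seed)
    planted = np.asarray(planted, dtype=float)
    mu = rng.lognormal(np.log(200), 1.0, n_species)
    counts = rng.poisson(mu[:, None] * planted[None, :])
    cm = pd.DataFrame(counts, columns=[f"L{i}" for i in range(len(planted))])
    est = size_factors(cm).to_numpy()
    ratios = (est / est[1]) / (planted / planted[1])
    return float(np.max(np.abs(ratios - 1.0)))


#: Size factors used by the DE simulations — deliberately unequal.
_DE_SIZE_FACTORS = np.array([0.7, 1.0, 1.3, 0.8, 1.1, 1.2])
_DE_DISPERSION = 0.05
_DE_MEAN_LOG = np.log(100)


def _nb_counts(rng, mu_matrix, dispersion):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu_matrix))


def de_null_study(seed: int, n_species: int = 2000) -> float:
    """Fraction of raw p-values below 0.05 under a no-effect NB simulation."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(_DE_MEAN_LOG, 1.0, n_species)
    counts = _nb_counts(rng, mu[:, None] * _DE_SIZE_FACTORS[None, :],
                        _DE_DISPERSION)
    cm = pd.DataFrame(counts, columns=[f"L{i}" for i in range(6)])
    groups = {f"L{i}": ("A" if i < 3 else "B") for i in range(6)}
    res = de_test(cm, groups)
    return float((res.table["pvalue"] < 0.05).mean())


def de_power_study(
    seed: int, n_species: int = 2000, n_planted: int = 50, fold: float = 8.0
) -> float:
    """Fraction of planted fold-changes recovered at BH-adjusted p < 0.05."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(_DE_MEAN_LOG, 1.0, n_species)
    planted = rng.choice(n_species, n_planted, replace=False)
    fold_vec = np.ones(n_species)
    fold_vec[planted] = fold
    mu_a = mu[:, None] * _DE_SIZE_FACTORS[None, :3]
    mu_b = (mu * fold_vec)[:, None] * _DE_SIZE_FACTORS[None, 3:]
    counts = np.concatenate(
        [_nb_counts(rng, mu_a, _DE_DISPERSION), _nb_counts(rng, mu_b, _DE_DISPERSION)],
        axis=1,
    )
    cm = pd.DataFrame(counts, columns=[f"L{i}" for i in range(6)])
    groups = {f"L{i}": ("A" if i < 3 else "B") for i in range(6)}
    res = de_test(cm, groups)
    return float((res.table["padj"].to_numpy()[planted] < 0.05).mean())
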
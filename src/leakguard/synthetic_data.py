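"""VCF-level emulation of a spike-in tumour/normal benchmarking design.

A gold-standard benchmark spikes known germline and somatic variants into
sequencing data so that every submitted call can be judged exactly.  This
module emulates that design at the *variant* level — no reads, no BAMs:

* :func:`simulate_truth` draws disjoint germline and somatic truth sets at
  uniformly random genomic positions with uniformly random substitution
  types;
* :func:`simulate_caller` emulates one somatic caller: it recovers each truth
  somatic variant with probability ``sensitivity``, emits each germline
  variant as a (leaked) somatic call with probability ``leak_rate`` — a
  variant-level proxy for the effect of infiltrating normal cells — and adds
  a Poisson number of novel false-positive calls at positions untouched by
  either truth set;
* :func:`simulate_cohort` runs a grid of caller profiles over shared truths
  and scores every submission, producing the table that the cohort
  statistics consume.

Default scales mirror a whole-genome spike-in benchmark at desk size:
thousands of spiked-in variants and a caller with 90% sensitivity.  The
default ``leak_rate`` of 0.001 makes the typical submission leak a handful
of germline variants out of thousands, matching the regime where leakage is
rare but nonzero.

Reproducibility: every run consumes a single numpy Generator seeded from
``(config.seed, caller_seed)``, and draws happen in a fixed documented order
(somatic recovery, then germline leakage, then novel-FP count, then novel-FP
placement), so outputs are bit-identical across platforms for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import CapacityError
from .evaluation import EvaluationResult, score
from .cohort_analysis import SubmissionRecord
from .vcf_io import VariantKey, VariantSet, variant_sort_key

__all__ = [
    "SNV_SUBSTITUTIONS",
    "SimulationConfig",
    "CallerProfile",
    "SimulatedSubmission",
    "SimulatedCohort",
    "simulate_truth",
    "simulate_caller",
    "simulate_cohort",
    "write_vcf",
]

# the 12 ordered ref->alt substitution pairs
SNV_SUBSTITUTIONS = tuple(
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic tumour/normal + caller generator.

    ``fp_rate`` is the *expected count* of novel false calls per submission
    (Poisson), not a per-site probability.
    """

    n_chroms: int = 22
    chrom_length: int = 1_000_000
    n_germline: int = 5_000
    n_somatic: int = 4_000
    sensitivity: float = 0.9
    fp_rate: float = 50.0
    leak_rate: float = 0.001
    seed: int = 2018

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("n_chroms and chrom_length must be positive")
        if min(self.n_germline, self.n_somatic) < 0:
            raise ValueError("spike-in counts must be non-negative")
        for name in ("sensitivity", "leak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")

    @property
    def capacity(self) -> int:
        return self.n_chroms * self.chrom_length


def _positions_to_keys(flat_positions: np.ndarray, subs: np.ndarray, chrom_length: int):
    keys = []
    for flat, sub_idx in zip(flat_positions.tolist(), subs.tolist()):
        chrom = flat // chrom_length + 1
        pos = flat % chrom_length + 1
        ref, alt = SNV_SUBSTITUTIONS[sub_idx]
        keys.append(VariantKey(str(chrom), pos, ref, alt))
    return keys


def simulate_truth(config: SimulationConfig) -> tuple:
    """Draw disjoint germline and somatic truth sets, reproducibly from the seed.

    Positions are sampled uniformly without replacement across the genome
    (so the two sets are position-disjoint by construction); substitution
    types are uniform over the 12 ordered pairs.
    """
    n_total = config.n_germline + config.n_somatic
    if n_total > config.capacity:
        raise CapacityError(
            f"requested {n_total} spike-ins but the genome holds only "
            f"{config.capacity} sites"
        )
    rng = np.random.default_rng(config.seed)
    flat = rng.choice(config.capacity, size=n_total, replace=False)
    subs = rng.integers(0, len(SNV_SUBSTITUTIONS), size=n_total)
    keys = _positions_to_keys(flat, subs, config.chrom_length)
    germline = VariantSet(frozenset(keys[: config.n_germline]), "truth-germline")
    somatic = VariantSet(frozenset(keys[config.n_germline:]), "truth-somatic")
    return germline, somatic


@dataclass(frozen=True)
class SimulatedSubmission:
    """One simulated caller output with its generator-side bookkeeping."""

    predicted: VariantSet
    called_tp: frozenset
    leaked: frozenset
    novel_fp: frozenset
    config: SimulationConfig
    caller_seed: int


def simulate_caller(
    truth_somatic: VariantSet,
    truth_germline: VariantSet,
    config: SimulationConfig,
    caller_seed: int = 0,
) -> SimulatedSubmission:
    """Emulate one somatic caller run over the truth sets.

    Draw order (single stream seeded by ``(config.seed, caller_seed)``):
    Bernoulli(sensitivity) per somatic truth key in sorted order, then
    Bernoulli(leak_rate) per germline key in sorted order, then the
    Poisson(fp_rate) novel-call count, then novel-call placement.  Novel
    calls are resampled if their position collides with either truth set or
    an earlier novel call, keeping the TP/leak/other-FP partition exact.
    """
    rng = np.random.default_rng([config.seed, caller_seed])
    som_sorted = truth_somatic.sorted_keys()
    germ_sorted = truth_germline.sorted_keys()

    take_som = rng.random(len(som_sorted)) < config.sensitivity
    called_tp = frozenset(k for k, t in zip(som_sorted, take_som) if t)
    take_germ = rng.random(len(germ_sorted)) < config.leak_rate
    leaked = frozenset(k for k, t in zip(germ_sorted, take_germ) if t)

    n_novel = int(rng.poisson(config.fp_rate))
    occupied = {(k.chrom, k.pos) for k in truth_somatic} | {
        (k.chrom, k.pos) for k in truth_germline
    }
    novel = set()
    while len(novel) < n_novel:
        flat = int(rng.integers(0, config.capacity))
        chrom = str(flat // config.chrom_length + 1)
        pos = flat % config.chrom_length + 1
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        ref, alt = SNV_SUBSTITUTIONS[int(rng.integers(0, len(SNV_SUBSTITUTIONS)))]
        novel.add(VariantKey(chrom, pos, ref, alt))

    predicted = VariantSet(
        called_tp | leaked | frozenset(novel), f"simulated-caller-{caller_seed}"
    )
    return SimulatedSubmission(
        predicted=predicted, called_tp=called_tp, leaked=leaked,
        novel_fp=frozenset(novel), config=config, caller_seed=caller_seed,
    )


def write_vcf(variants: VariantSet, path: Union[str, Path], source: str = "leakguard-simulate") -> int:
    """Write a minimal valid VCF 4.2 for a variant set; returns record count."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    keys = variants.sorted_keys()
    lines += [f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t." for k in keys]
    path.write_text("\n".join(lines) + "\n")
    return len(keys)


@dataclass(frozen=True)
class CallerProfile:
    """One team's caller characteristics for cohort simulation."""

    team_id: str
    sensitivity: float
    fp_rate: float
    leak_rate: float
    n_submissions: int = 1
    is_admin: bool = False


@dataclass(frozen=True)
class SimulatedCohort:
    truths: dict            # tumour -> (germline VariantSet, somatic VariantSet)
    submissions: dict       # (tumour, submission_id) -> SimulatedSubmission
    results: dict           # (tumour, submission_id) -> EvaluationResult
    records: list           # SubmissionRecord rows, cohort_analysis-ready


def simulate_cohort(
    grid: Sequence[CallerProfile],
    config: SimulationConfig,
    tumours: Sequence[str] = ("IS1", "IS2", "IS3"),
    base_seed: Optional[int] = None,
) -> SimulatedCohort:
    """Simulate a full challenge: shared truths per tumour, one submission per
    grid entry (times ``n_submissions``), everything scored end-to-end.

    Each tumour gets its own truth sets (derived seed), and every submission
    a distinct caller seed, so replicates are independent but reproducible.
    """
    base_seed = config.seed if base_seed is None else base_seed
    truths = {}
    for t_idx, tumour in enumerate(tumours):
        t_config = replace(config, seed=base_seed + 1000 * (t_idx + 1))
        truths[tumour] = simulate_truth(t_config)

    submissions: dict = {}
    records = []
    results: dict = {}
    caller_seed = 0
    for tumour in tumours:
        germline, somatic = truths[tumour]
        for profile in grid:
            for rep in range(profile.n_submissions):
                caller_seed += 1
                run_config = replace(
                    config,
                    sensitivity=profile.sensitivity,
                    fp_rate=profile.fp_rate,
                    leak_rate=profile.leak_rate,
                    seed=base_seed,
                )
                sim = simulate_caller(somatic, germline, run_config, caller_seed)
                result = score(sim.predicted, somatic, germline)
                submission_id = f"{tumour}.{profile.team_id}.{rep + 1}"
                submissions[(tumour, submission_id)] = sim
                results[(tumour, submission_id)] = result
                records.append(
                    SubmissionRecord(
                        tumour=tumour,
                        submission_id=submission_id,
                        team_id=profile.team_id,
                        precision=result.precision,
                        recall=result.recall,
                        f1=result.f1,
                        leak_count=result.leak_count,
                        is_admin=profile.is_admin,
                    )
                )
    return SimulatedCohort(
        truths=truths, submissions=submissions, results=results, records=records
    )
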
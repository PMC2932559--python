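"""Synthetic communities, representative sequences, and reads with known structure.

The generator emulates the statistical shape the analysis assumes: a
metacommunity whose species abundances follow a two-component exponential
mixture (the same family the richness module fits), a small abundant core
shared by every replicate sample, and a large rare tail whose membership is
partially replaced, independently per replicate, by replicate-private
species (parameter ``rho``).  Reads are drawn multinomially per replicate at
a configurable depth.  ``rho = 0`` makes all replicates samples of one pool;
``rho = 1`` gives each replicate a private rare tail, reproducing the
qualitative signature of high rare-member beta diversity against a shared
abundant core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .otu_io import CountTable
from .rarity import percent_identity
from .read_qc import Read

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "STUDY_PRESET",
    "SMALL_PRESET",
    "generate_community",
    "generate_sequences",
    "SequenceBundle",
    "generate_reads_with_quality",
    "simulate_mixture_counts",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic metacommunity and its sampling."""
    S: int = 45000                      # metacommunity richness
    abundance_model: str = "geometric_mixture"   # or "lognormal"
    w: float = 0.7                      # mixture weight of the low-mean component
    mu1: float = 0.5                    # exponential means on the rate scale
    mu2: float = 50.0
    sigma: float = 2.0                  # lognormal shape (alternative model)
    core_fraction: float = 0.02         # top fraction of species shared as core
    rho: float = 0.8                    # rare-tail replacement fraction per replicate
    replicates: int = 4
    depths: tuple[int, ...] = (77361, 86240, 76693, 51836)
    seq_length: int = 250
    nunn_identity: float = 95.0         # planted identity targets (percent)
    unn_identity: float = 95.0
    category_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # NUNN/UNN/UN

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if len(self.depths) != self.replicates:
            raise ValueError("one depth per replicate required")
        if any(d < 1 for d in self.depths):
            raise ValueError("depths must be >= 1")
        if not all(0 < t <= 100 for t in (self.nunn_identity, self.unn_identity)):
            raise ValueError("identity targets must lie in (0, 100]")


STUDY_PRESET = SyntheticSpec()
SMALL_PRESET = replace(STUDY_PRESET, S=2000, depths=(5000, 5000, 5000, 5000))


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated community."""
    abundances: dict[str, float]            # metacommunity relative abundances
    core_ids: set[str]
    pools: list[set[str]]                   # species pool per replicate
    private_ids: set[str]                   # replicate-private replacements
    planted_labels: dict[str, str] = field(default_factory=dict)

    def shared_species(self) -> set[str]:
        out = set.intersection(*self.pools) if self.pools else set()
        return out


def _metacommunity_abundances(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.abundance_model == "geometric_mixture":
        which = rng.random(spec.S) < spec.w
        rates = np.where(which, rng.exponential(spec.mu1, spec.S),
                         rng.exponential(spec.mu2, spec.S))
    elif spec.abundance_model == "lognormal":
        rates = rng.lognormal(mean=0.0, sigma=spec.sigma, size=spec.S)
    else:
        raise ValueError(f"unknown abundance model {spec.abundance_model!r}")
    rates = np.maximum(rates, 1e-12)
    return rates / rates.sum()


def generate_community(spec: SyntheticSpec, seed: int | None = None) -> tuple[CountTable, SyntheticTruth]:
    """Generate a replicate community CountTable plus its ground truth."""
    rng = np.random.default_rng(seed)
    abund = _metacommunity_abundances(spec, rng)
    # object dtype: numpy fixed-width strings would truncate the longer
    # replicate-private ids assigned below
    ids = np.array([f"OTU{i:06d}" for i in range(spec.S)], dtype=object)
    order = np.argsort(abund)[::-1]
    n_core = max(1, int(round(spec.core_fraction * spec.S)))
    core_idx = set(order[:n_core].tolist())
    expected_core_reads = abund[list(core_idx)].sum() * min(spec.depths)
    if expected_core_reads < 1:
        import warnings
        warnings.warn("depth too small to expect any core reads")

    columns: dict[str, pd.Series] = {}
    pools: list[set[str]] = []
    private_ids: set[str] = set()
    for r in range(spec.replicates):
        replaced = np.zeros(spec.S, dtype=bool)
        tail = np.array([i not in core_idx for i in range(spec.S)])
        replaced[tail] = rng.random(int(tail.sum())) < spec.rho
        rep_ids = ids.copy()
        rep_ids[replaced] = [f"OTU{i:06d}_r{r + 1}" for i in np.nonzero(replaced)[0]]
        private_ids.update(rep_ids[replaced].tolist())
        probs = abund / abund.sum()
        counts = rng.multinomial(spec.depths[r], probs)
        col = pd.Series(counts, index=rep_ids)
        col = col.groupby(level=0).sum()   # defensive; rep ids are unique
        columns[f"q{r + 1}"] = col
        pools.append(set(rep_ids.tolist()))

    df = pd.DataFrame(columns).fillna(0).astype(np.int64)
    table = CountTable(df, drop_empty=True)
    truth = SyntheticTruth(
        abundances={ids[i]: float(abund[i]) for i in range(spec.S)},
        core_ids={ids[i] for i in core_idx},
        pools=pools,
        private_ids=private_ids,
    )
    return table, truth


# -- sequences ---------------------------------------------------------------

@dataclass
class SequenceBundle:
    rep_seqs: dict[str, str]          # rare + abundant representative sequences
    reference: dict[str, str]         # reference database (UNN parents)
    planted: dict[str, str]           # rare otu -> NUNN | UNN | UN


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate_to_identity(parent: str, target_identity: float,
                        rng: np.random.Generator) -> str:
    """Substitute enough positions to land near the target percent identity."""
    length = len(parent)
    n_mut = int(round((1.0 - target_identity / 100.0) * length))
    pos = rng.choice(length, size=n_mut, replace=False)
    seq = list(parent)
    for i in pos:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def generate_sequences(rare_ids: list[str], abundant_ids: list[str],
                       spec: SyntheticSpec, seed: int | None = None,
                       verify: bool = True, verify_max: int = 200) -> SequenceBundle:
    """Plant NUNN/UNN/UN structure into representative sequences.

    NUNN rare OTUs are mutated copies of abundant representatives at the
    ``nunn_identity`` target; UNN rare OTUs are mutated copies of
    reference-only parents; UN rare OTUs are unrelated random sequences.
    Achieved identities are spot-checked by alignment (up to ``verify_max``
    planted children) to land within 2 points of the target.
    """
    rng = np.random.default_rng(seed)
    rep: dict[str, str] = {o: _random_seq(spec.seq_length, rng) for o in abundant_ids}
    n_ref = max(len(rare_ids) // 2, 4)
    reference = {f"REF{i:05d}": _random_seq(spec.seq_length, rng) for i in range(n_ref)}
    ref_keys = list(reference)

    fractions = np.asarray(spec.category_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    labels = rng.choice(["NUNN", "UNN", "UN"], size=len(rare_ids), p=fractions)
    planted: dict[str, str] = {}
    to_verify: list[tuple[str, str, float]] = []
    for otu, label in zip(rare_ids, labels):
        planted[otu] = str(label)
        if label == "NUNN":
            parent = rep[abundant_ids[rng.integers(0, len(abundant_ids))]]
            child = _mutate_to_identity(parent, spec.nunn_identity, rng)
            to_verify.append((child, parent, spec.nunn_identity))
            rep[otu] = child
        elif label == "UNN":
            parent = reference[ref_keys[rng.integers(0, len(ref_keys))]]
            child = _mutate_to_identity(parent, spec.unn_identity, rng)
            to_verify.append((child, parent, spec.unn_identity))
            rep[otu] = child
        else:
            rep[otu] = _random_seq(spec.seq_length, rng)
    if verify and to_verify:
        idx = rng.permutation(len(to_verify))[:verify_max]
        for i in idx:
            child, parent, target = to_verify[i]
            hit = percent_identity(child, parent)
            if abs(hit.percent_identity - target) > 2.0:
                raise AssertionError(
                    f"planted identity {hit.percent_identity:.1f} missed target {target}")
    return SequenceBundle(rep_seqs=rep, reference=reference, planted=planted)


# -- reads with planted QC failures -------------------------------------------

DEFECTS = ("low_quality", "bad_primer", "ambiguous", "homopolymer", "short")


def _constrained_seq(length: int, rng: np.random.Generator, max_run: int = 4) -> str:
    """Random sequence with no homopolymer run longer than max_run."""
    out: list[str] = []
    run = 0
    for _ in range(length):
        choices = list("ACGT")
        if run >= max_run and out:
            choices.remove(out[-1])
        base = choices[rng.integers(0, len(choices))]
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


def generate_reads_with_quality(n_reads: int, primer: str,
                                defect_rates: dict[str, float] | None = None,
                                read_length: int = 150,
                                good_quality: int = 35,
                                seed: int | None = None) -> list[Read]:
    """Reads with controllable planted QC failures.

    ``defect_rates`` maps defect names (low_quality, bad_primer, ambiguous,
    homopolymer, short) to per-read probabilities; at most one defect is
    planted per read, so the expected attrition per filter is known.
    """
    rng = np.random.default_rng(seed)
    rates = {k: 0.0 for k in DEFECTS}
    if defect_rates:
        unknown = set(defect_rates) - set(DEFECTS)
        if unknown:
            raise ValueError(f"unknown defects: {sorted(unknown)}")
        rates.update(defect_rates)
    if sum(rates.values()) > 1:
        raise ValueError("defect rates sum to more than 1")
    probs = [rates[k] for k in DEFECTS] + [1.0 - sum(rates.values())]
    choices = rng.choice(len(probs), size=n_reads, p=probs)

    reads: list[Read] = []
    for i, c in enumerate(choices):
        defect = DEFECTS[c] if c < len(DEFECTS) else None
        body_len = read_length
        body = _constrained_seq(body_len, rng)
        seq = primer + body
        quality = good_quality
        if defect == "low_quality":
            quality = 24
        elif defect == "bad_primer":
            mutated = ("T" if primer[0] != "T" else "A") + primer[1:]
            seq = mutated + body
        elif defect == "ambiguous":
            pos = len(primer) + int(rng.integers(0, body_len))
            seq = seq[:pos] + "N" + seq[pos + 1:]
        elif defect == "homopolymer":
            pos = len(primer) + int(rng.integers(0, body_len - 9))
            seq = seq[:pos] + "A" * 9 + seq[pos + 9:]
        elif defect == "short":
            seq = primer + body[:40]
        reads.append(Read(f"read{i:06d}", seq, [quality] * len(seq)))
    return reads


# -- model-law simulation for recovery harnesses -------------------------------

def simulate_mixture_counts(S: int, w: float, mu1: float, mu2: float,
                            seed: int | None = None) -> np.ndarray:
    """Per-species counts drawn from the mixed-Poisson model itself.

    Rates are exponential-mixture draws, counts Poisson; the marginal count
    law is the two-component geometric mixture the richness module fits.
    Unobserved species (count 0) are included in the returned vector.
    """
    rng = np.random.default_rng(seed)
    which = rng.random(S) < w
    rates = np.where(which, rng.exponential(mu1, S), rng.exponential(mu2, S))
    return rng.poisson(rates)
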
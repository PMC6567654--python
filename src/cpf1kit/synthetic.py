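"""Synthetic matched/mismatched datasets and toy genomes with known truth.

Real AsCpf1 indel-frequency libraries are not redistributable here, so the
generators plant the qualitative structure those libraries exhibit and that
the classifiers are meant to recover:

* matched targets — activity falls with thymine content in the PAM-proximal
  seed (positions 5-10) and rises mildly with protospacer GC;
* mismatched pairs — each mismatch multiplies activity by a region penalty,
  strongest in the seed (positions 5-10), intermediate in the trunk
  (11-22), mild in the promiscuous tail (23-27);
* toy genomes — uniform background with planted near-duplicate protospacer
  copies at known loci, for off-target enumeration oracles.

Because the generating rule is known exactly, downstream tests can assert
recovery (which sequence of two is more active, which input columns matter,
which loci are off-targets) rather than eyeball plausibility.  Every knob
is explicit in :class:`GeneratorConfig`; nothing is hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encodings import BASES, MismatchRecord, TargetRecord, reverse_complement

__all__ = [
    "GeneratorConfig",
    "SEED_REGION",
    "TRUNK_REGION",
    "PROMISCUOUS_REGION",
    "simulate_on_target",
    "simulate_mismatch",
    "simulate_genome",
]

#: 1-based position ranges over the 27-nt site (PAM = 1-4).
SEED_REGION = range(5, 11)
TRUNK_REGION = range(11, 23)
PROMISCUOUS_REGION = range(23, 28)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators.

    On-target latent activity is
    ``logistic(beta0 - beta_t * nT(5..10) + beta_gc * (GC - 0.5))`` where
    nT counts thymines at seed positions and GC is the protospacer GC
    fraction; indel frequency is ``100 * activity + N(0, sigma)`` clipped
    to [0, 100].  Mismatched-pair frequency is ``100 * base_activity *
    prod(region multiplier per mismatch) + N(0, sigma)``, with the
    multiplier ordering seed < trunk < promiscuous.
    """

    n: int = 1251
    seed: int = 0
    beta0: float = 0.0
    beta_t: float = 0.8
    beta_gc: float = 1.0
    sigma: float = 5.0
    seed_mult: float = 0.1
    trunk_mult: float = 0.5
    prom_mult: float = 0.9
    min_mismatches: int = 1
    max_mismatches: int = 6
    base_activity_range: tuple[float, float] = (0.4, 1.0)

    def __post_init__(self) -> None:
        if not 0 <= self.seed_mult < self.trunk_mult < self.prom_mult <= 1:
            raise ValueError(
                "region multipliers must satisfy 0 <= seed < trunk <= prom <= 1 "
                f"(got {self.seed_mult}, {self.trunk_mult}, {self.prom_mult})"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _random_site(rng: np.random.Generator) -> str:
    pam = "TTT" + rng.choice(list(BASES))
    proto = "".join(rng.choice(list(BASES), size=23))
    return pam + proto


def _latent_activity(sequence: str, config: GeneratorConfig) -> float:
    proto = sequence[4:]
    n_t_seed = sum(1 for p in SEED_REGION if sequence[p - 1] == "T")
    gc = (proto.count("G") + proto.count("C")) / len(proto)
    return _logistic(
        config.beta0 - config.beta_t * n_t_seed + config.beta_gc * (gc - 0.5)
    )


def simulate_on_target(config: GeneratorConfig) -> list[TargetRecord]:
    """Matched 27-nt targets with indel frequencies driven by seed-region
    thymine depletion and protospacer GC."""
    if config.n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(config.seed)
    records = []
    for _ in range(config.n):
        seq = _random_site(rng)
        act = _latent_activity(seq, config)
        freq = float(np.clip(100.0 * act + rng.normal(0.0, config.sigma), 0.0, 100.0))
        records.append(TargetRecord(sequence=seq, indel_frequency=freq))
    return records


def _region_multiplier(position: int, config: GeneratorConfig) -> float:
    if position in SEED_REGION:
        return config.seed_mult
    if position in TRUNK_REGION:
        return config.trunk_mult
    return config.prom_mult


def simulate_mismatch(config: GeneratorConfig) -> list[MismatchRecord]:
    """Guide/target pairs with 1-6 mismatches and region-penalized activity."""
    if config.n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(config.seed)
    records = []
    positions = np.arange(5, 28)  # protospacer positions, 1-based
    for _ in range(config.n):
        guide = _random_site(rng)
        n_mm = int(rng.integers(config.min_mismatches, config.max_mismatches + 1))
        target = guide
        if n_mm:
            chosen = rng.choice(positions, size=n_mm, replace=False)
            target = list(guide)
            for pos in chosen:
                current = guide[pos - 1]
                target[pos - 1] = rng.choice([b for b in BASES if b != current])
            target = "".join(target)
        base = rng.uniform(*config.base_activity_range)
        mult = 1.0
        for pos in range(27):
            if guide[pos] != target[pos]:
                mult *= _region_multiplier(pos + 1, config)
        freq = float(np.clip(100.0 * base * mult + rng.normal(0.0, config.sigma),
                             0.0, 100.0))
        records.append(MismatchRecord(guide=guide, target=target,
                                      indel_frequency=freq))
    return records


def _mutate_protospacer(site: str, n_mismatches: int,
                        rng: np.random.Generator) -> str:
    """Substitute n bases of the protospacer, leaving the PAM intact."""
    seq = list(site)
    for pos in rng.choice(np.arange(4, 27), size=n_mismatches, replace=False):
        seq[pos] = rng.choice([b for b in BASES if b != seq[pos]])
    return "".join(seq)


def simulate_genome(
    length: int,
    planted: list[tuple[str, int, int]],
    seed: int = 0,
    max_tries: int = 1000,
):
    """Uniform-background genome with planted near-duplicate sites.

    Parameters
    ----------
    length : genome length (>= 1000)
    planted : list of (site_sequence, n_copies, n_mismatches); each copy of
        the 27-nt site is written with exactly ``n_mismatches`` protospacer
        substitutions, on a random strand, at a random locus that does not
        overlap previously planted loci.
    seed : RNG seed; the same seed reproduces the genome exactly.

    Returns
    -------
    (genome, truth) : the sequence and a list of dicts with keys
    ``site``, ``start``, ``end``, ``strand``, ``n_mismatches``,
    ``planted_sequence`` for every planted locus.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    genome = rng.choice(list(BASES), size=length)
    occupied: list[tuple[int, int]] = []
    truth = []
    for site, n_copies, n_mm in planted:
        if len(site) != 27:
            raise ValueError("planted sites must be 27 nt")
        for _ in range(n_copies):
            variant = _mutate_protospacer(site, n_mm, rng) if n_mm else site
            for attempt in range(max_tries):
                start = int(rng.integers(0, length - 27))
                span = (start, start + 27)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError(
                    f"could not place planted site after {max_tries} tries"
                )
            strand = str(rng.choice(["+", "-"]))
            written = variant if strand == "+" else reverse_complement(variant)
            genome[span[0] : span[1]] = list(written)
            occupied.append(span)
            truth.append({
                "site": site, "start": span[0], "end": span[1],
                "strand": strand, "n_mismatches": n_mm,
                "planted_sequence": variant,
            })
    return "".join(genome), truth
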
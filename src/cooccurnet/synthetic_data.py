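"""Synthetic survey generator with known ground truth.

Emulates an online survey in which each participant lists the social groups
they belong to (up to 10) and, for each group, the behaviours typical of its
members. Marginal shapes follow the survey this package was designed
around: 286 participants, a heavy-tailed vocabulary of 138 identity labels
and 83 behaviour labels, identities per participant with mean 5.20 and SD
1.95 on 1-10, behaviours per identity with mean 2.06 and SD 1.26 on 1-10.

Structure can be planted on top of the independent baseline:

* **identity blocks** — sets of identities whose within-block co-reporting
  is boosted (ground truth for community recovery);
* **preferred / avoided dyads** — pairs forced to co-occur more (or less)
  than their popularity predicts (ground truth for dyad tests);
* **behaviour profiles** — each identity draws behaviours from a mixture of
  a shared population pool and an identity-specific pool; identities in the
  same block share their specific pool, so blocks also share behaviours.

``null_dataset`` disables all structure: identities are sampled
independently given label popularity, behaviours independently given their
marginal frequencies — the configuration under which permutation tests
should reject at their nominal rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize

from .survey_io import Participant, SurveyDataset


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CountDistribution:
    """Discretized truncated-normal integer distribution matched to (mean, sd)."""

    mean: float
    sd: float
    min: int
    max: int

    def pmf(self) -> np.ndarray:
        return _discretized_normal_pmf(self.mean, self.sd, self.min, self.max)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        support = np.arange(self.min, self.max + 1)
        return rng.choice(support, size=size, p=self.pmf())


@lru_cache(maxsize=32)
def _discretized_normal_pmf(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Moment-match a normal density discretized onto {lo..hi} to (mean, sd).

    The pmf is the normal density evaluated at the integers and renormalized;
    (mu, sigma) are solved so the discrete mean and SD hit their targets.
    """
    support = np.arange(lo, hi + 1, dtype=float)

    def pmf_for(mu: float, log_sigma: float) -> np.ndarray:
        sigma = np.exp(log_sigma)
        w = np.exp(-0.5 * ((support - mu) / sigma) ** 2)
        return w / w.sum()

    def residual(params: np.ndarray) -> np.ndarray:
        p = pmf_for(params[0], params[1])
        m = (p * support).sum()
        s = np.sqrt((p * (support - m) ** 2).sum())
        return np.array([m - mean, s - sd])

    sol = optimize.least_squares(residual, x0=np.array([mean, np.log(max(sd, 0.1))]))
    p = pmf_for(sol.x[0], sol.x[1])
    m = (p * support).sum()
    s = np.sqrt((p * (support - m) ** 2).sum())
    if abs(m - mean) > 0.05 or abs(s - sd) > 0.05:
        raise GeneratorConfigError(
            f"cannot match mean={mean}, sd={sd} on [{lo}, {hi}] "
            f"(achieved mean={m:.3f}, sd={s:.3f})"
        )
    return p


@dataclass(frozen=True)
class PlantedDyad:
    pair: tuple[str, str]
    type: str  # "preferred" | "avoided"
    effect: float = 0.9  # conditional co-report (preferred) / removal (avoided) probability

    def __post_init__(self) -> None:
        if self.type not in ("preferred", "avoided"):
            raise GeneratorConfigError(f"unknown dyad type: {self.type!r}")
        if not (0 <= self.effect <= 1):
            raise GeneratorConfigError("dyad effect must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedBlock:
    identities: tuple[str, ...]
    #: probability that a participant holding one block member co-reports
    #: each other member (each missing mate pulled in independently)
    boost: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.boost <= 1):
            raise GeneratorConfigError("block boost must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 286
    identity_vocab_size: int = 138
    behaviour_vocab_size: int = 83
    identities_per_participant: CountDistribution = CountDistribution(5.20, 1.95, 1, 10)
    behaviours_per_identity: CountDistribution = CountDistribution(2.06, 1.26, 1, 10)
    #: Zipf exponents of label base popularity. The two vocabularies have
    #: distinctly different tail weights: behaviours are mentioned ~2x as
    #: often per label as identities, so reproducing realistic filtered node
    #: counts needs a steeper behaviour tail.
    identity_popularity: float = 1.3
    behaviour_popularity: float = 1.9
    planted_identity_blocks: tuple[PlantedBlock, ...] = ()
    planted_dyads: tuple[PlantedDyad, ...] = ()
    #: probability a behaviour draw comes from the shared population pool
    #: rather than the identity's own pool (1.0 = fully shared, no structure)
    behaviour_overlap: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.identities_per_participant.max > self.identity_vocab_size:
            raise GeneratorConfigError("identity vocabulary smaller than max count")
        if self.behaviours_per_identity.max > self.behaviour_vocab_size:
            raise GeneratorConfigError("behaviour vocabulary smaller than max count")
        if not (0 <= self.behaviour_overlap <= 1):
            raise GeneratorConfigError("behaviour_overlap must lie in [0, 1]")
        vocab = set(self.identity_labels())
        blocked: dict[str, int] = {}
        for bi, block in enumerate(self.planted_identity_blocks):
            if len(block.identities) > self.identity_vocab_size:
                raise GeneratorConfigError("block larger than identity vocabulary")
            for ident in block.identities:
                if ident not in vocab:
                    raise GeneratorConfigError(f"unknown identity in block: {ident!r}")
                if ident in blocked:
                    raise GeneratorConfigError(f"identity in two blocks: {ident!r}")
                blocked[ident] = bi
        for dyad in self.planted_dyads:
            a, b = dyad.pair
            for lbl in (a, b):
                if lbl not in vocab:
                    raise GeneratorConfigError(f"unknown identity in dyad: {lbl!r}")
            if a == b:
                raise GeneratorConfigError("dyad must name two distinct identities")
            if (
                dyad.type == "avoided"
                and a in blocked
                and b in blocked
                and blocked[a] == blocked[b]
            ):
                raise GeneratorConfigError(
                    f"avoided dyad {dyad.pair} lies inside planted block {blocked[a]}"
                )

    def identity_labels(self) -> list[str]:
        return [f"identity_{i + 1:03d}" for i in range(self.identity_vocab_size)]

    def behaviour_labels(self) -> list[str]:
        return [f"behaviour_{i + 1:03d}" for i in range(self.behaviour_vocab_size)]

    def base_weights(self, vocab_size: int, exponent: float) -> np.ndarray:
        ranks = np.arange(1, vocab_size + 1, dtype=float)
        w = ranks ** (-exponent)
        return w / w.sum()

    def identity_base_weights(self) -> np.ndarray:
        return self.base_weights(self.identity_vocab_size, self.identity_popularity)

    def behaviour_base_weights(self) -> np.ndarray:
        return self.base_weights(self.behaviour_vocab_size, self.behaviour_popularity)


@dataclass
class GroundTruth:
    blocks: list[list[str]]
    preferred_dyads: list[tuple[str, str]]
    avoided_dyads: list[tuple[str, str]]
    behaviour_overlap: float
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "blocks": self.blocks,
                    "preferred_dyads": self.preferred_dyads,
                    "avoided_dyads": self.avoided_dyads,
                    "behaviour_overlap": self.behaviour_overlap,
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _esp_suffix_table(w: np.ndarray, kmax: int) -> np.ndarray:
    """Suffix elementary symmetric polynomials: E[i, j] = e_j(w_i .. w_{N-1})."""
    n = len(w)
    e = np.zeros((n + 1, kmax + 1))
    e[:, 0] = 1.0
    for i in range(n - 1, -1, -1):
        e[i, 1:] = e[i + 1, 1:] + w[i] * e[i + 1, :-1]
    return e


def _cps_sample(
    w: np.ndarray, k: int, e: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Conditional Poisson sampling of k distinct indices.

    Draws a size-k subset S with probability proportional to the product of
    its label weights, P(S) ∝ prod_{l in S} w_l. Unlike sequential draws
    without replacement, this makes the full samples-by-items matrix
    conditionally uniform given its margins, so datastream permutation tests
    on unstructured data are calibrated.
    """
    out: list[int] = []
    need = k
    for i in range(len(w)):
        if need == 0:
            break
        denom = e[i, need]
        p = 1.0 if denom == 0 else w[i] * e[i + 1, need - 1] / denom
        if rng.random() < p:
            out.append(i)
            need -= 1
    return out


def _sample_identities(
    config: GeneratorConfig,
    esp: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    """One participant's identity list.

    The base set is a conditional Poisson draw (structureless given label
    popularity and list length); planted blocks and dyads then edit the set
    while preserving its size.
    """
    labels = config.identity_labels()
    base = config.identity_base_weights()
    ix = {lbl: i for i, lbl in enumerate(labels)}
    block_of = {
        ident: bi
        for bi, block in enumerate(config.planted_identity_blocks)
        for ident in block.identities
    }
    planted_labels = {l for d in config.planted_dyads for l in d.pair} | set(block_of)

    k = int(config.identities_per_participant.sample(rng, 1)[0])
    chosen_set = {labels[j] for j in _cps_sample(base, k, esp, rng)}

    def swap_in(new: str) -> None:
        """Replace a random non-planted member with ``new`` (size preserved)."""
        candidates = sorted(chosen_set - planted_labels - {new})
        if not candidates or new in chosen_set:
            return
        chosen_set.discard(candidates[int(rng.integers(len(candidates)))])
        chosen_set.add(new)

    def swap_out(old: str) -> None:
        chosen_set.discard(old)
        avail = [l for l in labels if l not in chosen_set and l not in planted_labels]
        pw = np.array([base[ix[l]] for l in avail])
        chosen_set.add(avail[int(rng.choice(len(avail), p=pw / pw.sum()))])

    for bi, block in enumerate(config.planted_identity_blocks):
        members = set(block.identities)
        if chosen_set & members:
            for mate in sorted(members - chosen_set):
                if rng.random() < block.boost:
                    swap_in(mate)
    for dyad in config.planted_dyads:
        a, b = dyad.pair
        if dyad.type == "preferred":
            has_a, has_b = a in chosen_set, b in chosen_set
            if has_a != has_b and rng.random() < dyad.effect:
                swap_in(b if has_a else a)
        else:  # avoided
            if a in chosen_set and b in chosen_set and rng.random() < dyad.effect:
                swap_out(b)

    # keep popularity-rank order within the response list
    return sorted(chosen_set, key=lambda l: ix[l])


def _behaviour_pools(config: GeneratorConfig, master_seed: int) -> dict[str, np.ndarray]:
    """Identity-specific behaviour weight vectors (block-mates share theirs)."""
    base = config.behaviour_base_weights()
    block_of = {
        ident: bi
        for bi, block in enumerate(config.planted_identity_blocks)
        for ident in block.identities
    }
    pools: dict[str, np.ndarray] = {}
    perm_cache: dict[tuple[int, int], np.ndarray] = {}
    for i, ident in enumerate(config.identity_labels()):
        # block-mates share one pool; seeds are stable integers, never hashes
        key = (1, block_of[ident]) if ident in block_of else (0, i)
        if key not in perm_cache:
            sub = np.random.default_rng((master_seed, 7, *key))
            perm_cache[key] = sub.permutation(config.behaviour_vocab_size)
        pools[ident] = base[perm_cache[key]]
    return pools


def generate(config: GeneratorConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Draw a survey dataset plus the ground truth of its planted structure."""
    master_seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(master_seed)
    beh_labels = config.behaviour_labels()
    beh_base = config.behaviour_base_weights()
    pools = _behaviour_pools(config, master_seed)
    kmax_i = config.identities_per_participant.max
    kmax_b = config.behaviours_per_identity.max
    esp_idents = _esp_suffix_table(config.identity_base_weights(), kmax_i)
    esp_behs: dict[str, np.ndarray] = {}

    participants: list[Participant] = []
    for p in range(config.n_participants):
        idents = _sample_identities(config, esp_idents, rng)
        behs: dict[str, list[str]] = {}
        for ident in idents:
            m = int(config.behaviours_per_identity.sample(rng, 1)[0])
            if ident not in esp_behs:
                mix = (
                    config.behaviour_overlap * beh_base
                    + (1 - config.behaviour_overlap) * pools[ident]
                )
                esp_behs[ident] = _esp_suffix_table(mix, kmax_b)
            mix = (
                config.behaviour_overlap * beh_base
                + (1 - config.behaviour_overlap) * pools[ident]
            )
            picks = _cps_sample(mix, m, esp_behs[ident], rng)
            behs[ident] = [beh_labels[j] for j in sorted(picks)]
        participants.append(Participant(f"p{p + 1:03d}", idents, behs))

    truth = GroundTruth(
        blocks=[list(b.identities) for b in config.planted_identity_blocks],
        preferred_dyads=[d.pair for d in config.planted_dyads if d.type == "preferred"],
        avoided_dyads=[d.pair for d in config.planted_dyads if d.type == "avoided"],
        behaviour_overlap=config.behaviour_overlap,
        seed=config.seed,
    )
    return SurveyDataset(participants), truth


def null_dataset(config: GeneratorConfig) -> SurveyDataset:
    """A dataset with all planted structure disabled.

    Identities are independent given label popularity; behaviours are
    independent given their marginal frequencies.
    """
    null_config = replace(
        config,
        planted_identity_blocks=(),
        planted_dyads=(),
        behaviour_overlap=1.0,
    )
    dataset, _ = generate(null_config)
    return dataset
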
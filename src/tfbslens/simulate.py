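"""Synthetic TF/TFBS worlds with the statistical structure the analysis assumes.

A world mimics the shape of a curated TF binding-site compendium without any
external data:

* TF **families** with graded protein similarity (a root protein mutated at a
  high between-family rate into family ancestors, then at a low within-family
  rate into members), so within-family identity exceeds between-family
  identity;
* per-TF **PWMs** derived from a family-ancestral matrix (Dirichlet around a
  family consensus, then small per-member perturbations), so similar TFs get
  similar binding models — the sequence-level correspondence signal;
* **positive instances** sampled column-wise from each TF's PWM with a short
  family-specific flank appended on the right (lightly mutated per site, long
  enough to hold one catalog motif) — so the sequence, structure and
  evolution signals coexist without destroying one another and sites of one
  family stay mutually alignable;
* a **promoter corpus** from a stated background process (i.i.d. draws with
  base probabilities A/C/G/T = 0.30/0.20/0.20/0.30 — a degenerate Markov
  process; the pipeline still fits its order-3 chain to this corpus);
* a **conserved-motif catalog** and per-TF motif embedding rank-matched
  (Gaussian copula) to ortholog counts: one latent uniform drives both the
  TF's embedding probability and the conservation score of its assigned
  catalog motif (the catalog is score-sorted and indexed by that latent), so
  the mean evolution feature of a TF's sites is a monotone function of the
  latent and the chosen Spearman correlation with TF conservation
  materializes without multiplicative score noise;
* optional **structure classes** (:func:`plant_structure_classes`) whose PWMs
  are biased toward class-specific base composition, calibrated analytically
  so the best structure attributes separate classes by a requested number of
  within-class standard deviations.

Everything is bit-reproducible under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import DNA_BASES, IUPAC, decode_dna
from .background import (
    assemble_instance_sets,
    average_site_length,
    build_negative_pool,
    fit_markov,
)
from .containers import InstanceSet, SequenceRecord
from .features import PWM, MotifCatalog

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROMOTER_BASE_PROBS = np.array([0.30, 0.20, 0.20, 0.30])
_TWOFOLD_CODES = "RYSWKM"

__all__ = [
    "WorldConfig",
    "TFRecord",
    "SyntheticWorld",
    "generate_world",
    "sample_sites",
    "plant_structure_classes",
    "sample_conservation_pairs",
    "build_instance_bundles",
]


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    Defaults are sized to a desk-scale rendition of the source compendium's
    shape: a few families of TFs, each with 30 verified sites (the inclusion
    rule demands more than 10), sharp PWMs, a 174-motif conservation catalog
    and a modest planted TF/TFBS conservation correlation.
    """

    n_families: int = 4
    tfs_per_family: int = 5
    protein_length: int = 120
    within_family_divergence: float = 0.05
    between_family_divergence: float = 0.5
    pwm_length: int = 16
    pwm_sharpness: float = 20.0
    sites_per_tf: int = 30
    flank_length: int = 10
    flank_mutation_rate: float = 0.1
    n_motifs: int = 174
    motif_length: int = 10
    motif_score_range: tuple[float, float] = (1.0, 100.0)
    embed_prob_range: tuple[float, float] = (0.3, 0.95)
    planted_rho: float = 0.3
    n_reference_species: int = 96
    ortholog_rate: float = 0.35
    n_promoters: int = 50
    promoter_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_family_divergence <= 1):
            raise ValueError("within_family_divergence must be in [0, 1]")
        if not (0 <= self.between_family_divergence <= 1):
            raise ValueError("between_family_divergence must be in [0, 1]")
        if self.within_family_divergence >= self.between_family_divergence:
            raise ValueError("within-family divergence must be below between-family")
        if self.sites_per_tf < 10:
            raise ValueError("sites_per_tf must be >= 10 (study inclusion rule)")
        if self.pwm_length < 2:
            raise ValueError("pwm_length must be >= 2")
        if self.motif_length > self.flank_length:
            raise ValueError("motif_length must fit in the flank")
        if not (-1 <= self.planted_rho <= 1):
            raise ValueError("planted_rho must be in [-1, 1]")


@dataclass
class TFRecord:
    tf_id: str
    family: str
    protein: SequenceRecord
    pwm: PWM
    ortholog_count: int
    embed_prob: float
    sites: list[str]
    class_label: str | None = None
    assigned_motif: int | None = None


@dataclass
class SyntheticWorld:
    config: WorldConfig
    tfs: list[TFRecord]
    promoters: list[str]
    catalog: MotifCatalog
    truth_families: pd.DataFrame = field(repr=False, default=None)
    truth_conservation: pd.DataFrame = field(repr=False, default=None)

    @property
    def tf_ids(self) -> list[str]:
        return [tf.tf_id for tf in self.tfs]

    def tf(self, tf_id: str) -> TFRecord:
        for tf in self.tfs:
            if tf.tf_id == tf_id:
                return tf
        raise KeyError(tf_id)

    def site_owner_map(self, site_ids_of: dict[str, list[str]]) -> dict[str, str]:
        return {sid: tf for tf, sids in site_ids_of.items() for sid in sids}


# ---------------------------------------------------------------------------
# Primitive samplers
# ---------------------------------------------------------------------------


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _family_pwm(consensus_idx: np.ndarray, sharpness: float, rng: np.random.Generator) -> np.ndarray:
    cols = np.empty((len(consensus_idx), 4))
    for j, c in enumerate(consensus_idx):
        alpha = np.ones(4)
        alpha[c] += sharpness
        cols[j] = rng.dirichlet(alpha)
    return cols

_MEMBER_CONCENTRATION = 60.0


def _member_pwm(ancestral: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cols = np.empty_like(ancestral)
    for j in range(ancestral.shape[0]):
        cols[j] = rng.dirichlet(_MEMBER_CONCENTRATION * ancestral[j] + 0.3)
    return cols


def sample_sites(pwm: PWM, n: int, seed: int | np.random.Generator | None = None) -> list[str]:
    """Draw ``n`` segments column-wise from the PWM (positions independent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = pwm.freqs.cumsum(axis=1)
    u = rng.random((n, len(pwm)))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    return [decode_dna(row) for row in np.minimum(idx, 3)]


def _background_segment(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=PROMOTER_BASE_PROBS)
    return decode_dna(idx)


def _instantiate_motif(consensus: str, rng: np.random.Generator) -> str:
    out = []
    for c in consensus:
        bases = IUPAC[c]
        out.append(bases[rng.integers(len(bases))] if len(bases) > 1 else bases)
    return "".join(out)


def _make_catalog(config: WorldConfig, rng: np.random.Generator) -> MotifCatalog:
    """Score-sorted (ascending) catalog of degenerate motifs."""
    motifs = []
    scores = np.sort(rng.uniform(*config.motif_score_range, size=config.n_motifs))
    for score in scores:
        letters = [DNA_BASES[i] for i in rng.integers(0, 4, size=config.motif_length)]
        pos = rng.integers(config.motif_length)
        letters[pos] = _TWOFOLD_CODES[rng.integers(len(_TWOFOLD_CODES))]
        motifs.append(("".join(letters), float(score)))
    return MotifCatalog(motifs)


def _assemble_site(
    core: str,
    config: WorldConfig,
    embed: bool,
    motif_consensus: str | None,
    rng: np.random.Generator,
    flank_template: str | None = None,
) -> str:
    """Core (PWM sample) plus right-hand flank.

    The flank copies the family template with per-base mutations (keeping
    sites of one family mutually alignable); with no template it is drawn
    from the background base distribution. An embedded catalog motif
    overwrites a window of the flank.
    """
    if flank_template is None:
        flank = list(_background_segment(config.flank_length, rng))
    else:
        flank = list(flank_template)
        hits = np.flatnonzero(rng.random(len(flank)) < config.flank_mutation_rate)
        for i in hits:
            flank[i] = DNA_BASES[rng.integers(4)]
    if embed and motif_consensus is not None:
        concrete = _instantiate_motif(motif_consensus, rng)
        off = rng.integers(config.flank_length - len(concrete) + 1)
        flank[off : off + len(concrete)] = list(concrete)
    return core + "".join(flank)


def _copula_draws(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform pairs whose ranks carry Spearman correlation ``rho``.

    Uses the bivariate-normal relation r = 2 sin(pi rho / 6) between the
    Pearson correlation of the latent normals and the Spearman correlation of
    their Gaussian copula.
    """
    r = 2 * math.sin(math.pi * rho / 6)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(n)
    return stats.norm.cdf(z1), stats.norm.cdf(z2)


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world under ``config`` (see module doc)."""
    rng = np.random.default_rng(config.seed)
    n_tfs = config.n_families * config.tfs_per_family

    root = _random_protein(config.protein_length, rng)
    catalog = _make_catalog(config, rng)

    u_orth, u_embed = _copula_draws(n_tfs, config.planted_rho, rng)
    counts = stats.binom.ppf(
        u_orth, config.n_reference_species, config.ortholog_rate
    ).astype(int)
    lo, hi = config.embed_prob_range
    embed_probs = lo + (hi - lo) * u_embed

    tfs: list[TFRecord] = []
    fam_rows = []
    k = 0
    for f in range(config.n_families):
        family = f"F{f + 1}"
        ancestor_protein = _mutate_protein(root, config.between_family_divergence, rng)
        consensus_idx = rng.integers(0, 4, size=config.pwm_length)
        ancestral_pwm = _family_pwm(consensus_idx, config.pwm_sharpness, rng)
        family_flank = _background_segment(config.flank_length, rng)
        for m in range(config.tfs_per_family):
            tf_id = f"TF{k + 1:03d}"
            protein = SequenceRecord(
                tf_id,
                _mutate_protein(ancestor_protein, config.within_family_divergence, rng),
                "protein",
            )
            pwm = PWM(_member_pwm(ancestral_pwm, rng), name=tf_id)
            # score-sorted catalog indexed by the copula latent: the TF's
            # assigned motif conservation is comonotone with its embedding rate
            motif_idx = (
                min(int(u_embed[k] * len(catalog)), len(catalog) - 1)
                if len(catalog)
                else None
            )
            cores = sample_sites(pwm, config.sites_per_tf, rng)
            embed_p = float(embed_probs[k])
            sites = [
                _assemble_site(
                    core,
                    config,
                    embed=bool(rng.random() < embed_p),
                    motif_consensus=(
                        catalog.motifs[motif_idx][0] if motif_idx is not None else None
                    ),
                    rng=rng,
                    flank_template=family_flank,
                )
                for core in cores
            ]
            tfs.append(
                TFRecord(
                    tf_id=tf_id,
                    family=family,
                    protein=protein,
                    pwm=pwm,
                    ortholog_count=int(counts[k]),
                    embed_prob=embed_p,
                    sites=sites,
                    assigned_motif=motif_idx,
                )
            )
            fam_rows.append({"tf_id": tf_id, "family": family})
            k += 1

    promoters = [
        _background_segment(config.promoter_length, rng)
        for _ in range(config.n_promoters)
    ]
    conservation = pd.DataFrame(
        {
            "tf_id": [tf.tf_id for tf in tfs],
            "ortholog_count": [tf.ortholog_count for tf in tfs],
            "tf_score": [
                tf.ortholog_count / config.n_reference_species for tf in tfs
            ],
            "embed_prob": [tf.embed_prob for tf in tfs],
        }
    )
    return SyntheticWorld(
        config=config,
        tfs=tfs,
        promoters=promoters,
        catalog=catalog,
        truth_families=pd.DataFrame(fam_rows),
        truth_conservation=conservation,
    )


def build_instance_bundles(
    world: SyntheticWorld, seed: int = 0, n_sets: int = 10, n_pool_sequences: int = 2
) -> dict[str, list[InstanceSet]]:
    """Balanced instance-set bundles for every TF of a world.

    Fits the order-3 background chain on the world's promoter corpus once,
    then per TF builds the negative pool at the TF's average site length and
    assembles ``n_sets`` balanced sets.
    """
    model = fit_markov(world.promoters, order=3, pseudocount=1.0)
    ss = np.random.SeedSequence(seed)
    bundles: dict[str, list[InstanceSet]] = {}
    for tf, child in zip(world.tfs, ss.spawn(len(world.tfs))):
        rng = np.random.default_rng(child)
        window = average_site_length(tf.sites)
        pool = build_negative_pool(model, window, n_pool_sequences, rng)
        bundles[tf.tf_id] = assemble_instance_sets(
            tf.sites, pool, n_sets=n_sets, seed=rng, tf_id=tf.tf_id
        )
    return bundles


# ---------------------------------------------------------------------------
# Structure classes
# ---------------------------------------------------------------------------


def _analytic_attribute_moments(
    col_probs: np.ndarray, tables: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expectation and variance of each attribute score for sites sampled
    column-wise from ``col_probs`` (L, 4).

    The attribute score is the mean of x over adjacent dinucleotides; the
    variance accounts for the covariance of adjacent terms (they share a
    base). ``tables`` is (n_attr, 4, 4).
    """
    P = col_probs
    L = P.shape[0]
    e_terms = np.einsum("ja,nab,jb->nj", P[:-1], tables, P[1:])
    e2_terms = np.einsum("ja,nab,jb->nj", P[:-1], tables**2, P[1:])
    var_terms = e2_terms - e_terms**2
    cov = np.zeros((tables.shape[0], max(L - 2, 0)))
    for j in range(L - 2):
        exy = np.einsum("a,b,c,nab,nbc->n", P[j], P[j + 1], P[j + 2], tables, tables)
        cov[:, j] = exy - e_terms[:, j] * e_terms[:, j + 1]
    mean = e_terms.mean(axis=1)
    var = (var_terms.sum(axis=1) + 2 * cov.sum(axis=1)) / (L - 1) ** 2
    return mean, var


def _planted_column_probs(
    consensus_idx: np.ndarray, q: float, flank_len: int
) -> np.ndarray:
    """Per-position base distributions of a planted-class site (core then
    right flank)."""
    L = len(consensus_idx) + flank_len
    P = np.tile(PROMOTER_BASE_PROBS, (L, 1))
    for j, c in enumerate(consensus_idx):
        P[j] = (1 - q) / 3
        P[j, c] = q
    return P


_PLANT_CONSENSUS_Q = 0.9  # per-site consensus probability in planted classes
# Within a planted class, members share the class consensus composition
# exactly: any per-TF drift puts TF-level sub-structure inside a class and the
# mixture criterion starts counting TFs instead of classes.
_PLANT_MEMBER_MUTATION = 0.0


def plant_structure_classes(
    world: SyntheticWorld,
    k_classes: int,
    separation: float,
    property_values: np.ndarray,
    class_sizes: list[int] | None = None,
    seed: int | None = None,
) -> SyntheticWorld:
    """Assign TFs to ``k_classes`` structure classes and rebuild their PWMs
    with class-biased base composition.

    Class ``c`` biases its consensus toward a marker base (A, C, G or T), with
    per-position marker probability ``p`` found by an analytic calibration:
    the 5th-best attribute's between-class gap divided by its within-class
    standard deviation (site-sampling noise plus TF-to-TF spread, both
    computed from the realized column distributions) must reach
    ``separation``. Raises when no ``p`` on the grid attains it.

    ``property_values`` is the (n_attr, 16) value matrix of the property
    table the downstream analysis will use.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if not 2 <= k_classes <= 4:
        raise ValueError("k_classes must be between 2 and 4 (one marker base per class)")
    cfg = world.config
    n_tfs = len(world.tfs)
    if class_sizes is None:
        base = n_tfs // k_classes
        class_sizes = [base + (1 if i < n_tfs % k_classes else 0) for i in range(k_classes)]
    if sum(class_sizes) != n_tfs:
        raise ValueError("class sizes must sum to the number of TFs")
    tables = np.asarray(property_values, dtype=float).reshape(-1, 4, 4)

    ss = np.random.SeedSequence(cfg.seed + 7919 if seed is None else seed)
    sites_per_tf = cfg.sites_per_tf

    for p in np.arange(0.50, 0.96, 0.05):
        rng = np.random.default_rng(ss)
        consensus_sets: list[list[np.ndarray]] = []
        for c in range(k_classes):
            # one class-level consensus template; members deviate only lightly,
            # so within-class spread is dominated by site-sampling noise
            marker = rng.random(cfg.pwm_length) < p
            template = rng.integers(0, 4, size=cfg.pwm_length)
            template[marker] = c
            members = []
            for _ in range(class_sizes[c]):
                cons = template.copy()
                hits = rng.random(cfg.pwm_length) < _PLANT_MEMBER_MUTATION
                cons[hits] = rng.integers(0, 4, size=int(hits.sum()))
                members.append(cons)
            consensus_sets.append(members)
        # analytic per-TF expected attribute vectors and site variances
        class_means, within_sds = [], []
        for c in range(k_classes):
            e_list, v_list = [], []
            for cons in consensus_sets[c]:
                P = _planted_column_probs(cons, _PLANT_CONSENSUS_Q, cfg.flank_length)
                mean, var = _analytic_attribute_moments(P, tables)
                e_list.append(mean)
                v_list.append(var / sites_per_tf)
            e_arr = np.stack(e_list)
            class_means.append(e_arr.mean(axis=0))
            within_sds.append(
                np.sqrt(e_arr.var(axis=0) + np.stack(v_list).mean(axis=0))
            )
        class_means = np.stack(class_means)  # (k, n_attr)
        within_sds = np.stack(within_sds)
        # standardized per-attribute gaps, worst class pair per attribute
        min_gaps = np.full(tables.shape[0], np.inf)
        pair_gaps = []
        for a in range(k_classes):
            for b in range(a + 1, k_classes):
                g = np.abs(class_means[a] - class_means[b]) / np.maximum(
                    within_sds[[a, b]].max(axis=0), 1e-12
                )
                pair_gaps.append(g)
                min_gaps = np.minimum(min_gaps, g)
        # clustering sees the joint space of the selected attributes: the
        # criterion is the worst class pair's Euclidean separation over the
        # 5 best attributes (standardized gaps add in quadrature)
        top = np.argsort(min_gaps)[::-1][: min(5, len(min_gaps))]
        joint = min(float(np.sqrt((g[top] ** 2).sum())) for g in pair_gaps)
        if joint >= separation:
            return _rebuild_with_classes(
                world, k_classes, class_sizes, consensus_sets, rng
            )
    raise ValueError(
        f"requested separation {separation} not attainable on the composition grid"
    )


def _rebuild_with_classes(
    world: SyntheticWorld,
    k_classes: int,
    class_sizes: list[int],
    consensus_sets: list[list[np.ndarray]],
    rng: np.random.Generator,
) -> SyntheticWorld:
    cfg = world.config
    class_names = [f"class{c + 1}" for c in range(k_classes)]
    new_tfs = []
    i = 0
    for c in range(k_classes):
        for cons in consensus_sets[c]:
            tf = world.tfs[i]
            q = _PLANT_CONSENSUS_Q
            freqs = np.full((cfg.pwm_length, 4), (1 - q) / 3)
            freqs[np.arange(cfg.pwm_length), cons] = q
            pwm = PWM(freqs, name=tf.tf_id)
            cores = sample_sites(pwm, cfg.sites_per_tf, rng)
            # no motif embedding here: the structure-level world isolates the
            # composition signal the analytic calibration models
            sites = [
                _assemble_site(
                    core,
                    cfg,
                    embed=False,
                    motif_consensus=None,
                    rng=rng,
                    flank_template=None,
                )
                for core in cores
            ]
            new_tfs.append(
                replace(tf, pwm=pwm, sites=sites, class_label=class_names[c])
            )
            i += 1
    truth = pd.DataFrame(
        {"tf_id": [t.tf_id for t in new_tfs], "class": [t.class_label for t in new_tfs]}
    )
    return SyntheticWorld(
        config=cfg,
        tfs=new_tfs,
        promoters=world.promoters,
        catalog=world.catalog,
        truth_families=truth,
        truth_conservation=world.truth_conservation,
    )


# ---------------------------------------------------------------------------
# Conservation pairs
# ---------------------------------------------------------------------------


def sample_conservation_pairs(
    n: int,
    planted_rho: float,
    seed: int = 0,
    config: WorldConfig | None = None,
) -> pd.DataFrame:
    """Generate ``n`` (tf_score, tfbs_score) pairs with a planted Spearman
    correlation.

    TF scores are ortholog counts over the reference-species count; TFBS
    scores are the measured mean evolution feature of actually generated
    sites whose motif-embedding probability is rank-matched to the TF score
    through the Gaussian copula. Measurement noise (finite sites per TF,
    heterogeneous motif scores) mildly attenuates the realized correlation
    relative to ``planted_rho``; at the package's default conditions the
    attenuation is well inside the sampling error at n = 270.
    """
    from .features import evolution_scores  # local import to avoid cycle churn

    cfg = config or WorldConfig(planted_rho=planted_rho, seed=seed)
    rng = np.random.default_rng(seed)
    catalog = _make_catalog(cfg, rng)
    u_orth, u_embed = _copula_draws(n, planted_rho, rng)
    counts = stats.binom.ppf(u_orth, cfg.n_reference_species, cfg.ortholog_rate).astype(int)
    lo, hi = cfg.embed_prob_range
    embed_probs = lo + (hi - lo) * u_embed

    site_len = cfg.pwm_length + cfg.flank_length
    all_sites: list[str] = []
    owners: list[int] = []
    for i in range(n):
        motif_idx = min(int(u_embed[i] * len(catalog)), len(catalog) - 1)
        consensus = catalog.motifs[motif_idx][0]
        for _ in range(cfg.sites_per_tf):
            seg = list(_background_segment(site_len, rng))
            if rng.random() < embed_probs[i]:
                concrete = _instantiate_motif(consensus, rng)
                off = rng.integers(site_len - len(concrete) + 1)
                seg[off : off + len(concrete)] = list(concrete)
            all_sites.append("".join(seg))
            owners.append(i)
    scores = evolution_scores(all_sites, catalog)
    owners_arr = np.asarray(owners)
    tfbs_scores = np.array(
        [scores[owners_arr == i].mean() for i in range(n)]
    )
    return pd.DataFrame(
        {
            "tf_id": [f"TF{i + 1:03d}" for i in range(n)],
            "tf_score": counts / cfg.n_reference_species,
            "tfbs_score": tfbs_scores,
        }
    )
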
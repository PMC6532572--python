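"""Seeded negative-binomial count simulation for a 2 genotype x 2 iron
condition x n replicate RNA-seq design.

The generator emulates the study design of the *clf* iron-deficiency
experiment: wild-type and *clf* (PRC2 H3K27 methyltransferase mutant)
roots under iron-sufficient (+Fe) and iron-deficient (-Fe, ferrozine)
conditions, three biological replicates per cell. FIT-dependent iron
acquisition genes carry a genotype x treatment interaction (stronger -Fe
induction in *clf*), PYE-dependent genes are induced comparably in both
genotypes, and background genes are not iron regulated.

Counts are negative binomial in the mean/dispersion parameterization of
the RNA-seq differential-expression literature:

    var = mu + alpha * mu**2

with ``alpha = 0`` degenerating to Poisson. Each gene has its own random
stream derived from (seed, gene index), so adding genes to a scenario
never perturbs the counts of earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("wildtype", "clf")
CONDITIONS = ("plusFe", "minusFe")

#: (-Fe/+Fe induction in wildtype, same in clf) for the three FIT-dependent
#: marker genes FIT, FRO2, IRT1, used as the ground-truth effect-size pool.
FIT_INDUCTION_PAIRS: tuple[tuple[float, float], ...] = (
    (3.9, 5.0),
    (13.7, 40.8),
    (11.3, 22.4),
)

#: Same for the PYE-dependent markers PYE, BTS, FRO3: induced under -Fe but
#: comparably so in both genotypes.
PYE_INDUCTION_PAIRS: tuple[tuple[float, float], ...] = (
    (4.9, 4.6),
    (5.9, 5.7),
    (17.5, 16.4),
)


@dataclass(frozen=True)
class SimGeneSpec:
    """Ground-truth parameters of one simulated gene.

    Parameters
    ----------
    gene_id
        Unique identifier.
    length_bp
        Transcript length in bases (>= 1); only used by FPKM.
    base_mean
        Expected +Fe count in wildtype at size factor 1 (> 0).
    induction_wt, induction_clf
        -Fe/+Fe mean ratio per genotype (> 0); 1 means not iron regulated.
    dispersion
        NB dispersion alpha >= 0 with var = mu + alpha * mu**2.
    set_label
        One of ``{"FIT", "PYE", "background"}``.
    """

    gene_id: str
    length_bp: int = 1000
    base_mean: float = 100.0
    induction_wt: float = 1.0
    induction_clf: float = 1.0
    dispersion: float = 0.05
    set_label: str = "background"

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError(f"{self.gene_id}: base_mean must be > 0")
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1")
        if self.dispersion < 0:
            raise ValueError(f"{self.gene_id}: dispersion must be >= 0")
        if self.induction_wt <= 0 or self.induction_clf <= 0:
            raise ValueError(f"{self.gene_id}: inductions must be > 0")

    def induction(self, genotype: str) -> float:
        return self.induction_wt if genotype == "wildtype" else self.induction_clf


@dataclass(frozen=True)
class SimDesign:
    """2x2 factorial design with ``n_reps`` replicates per cell."""

    n_reps: int = 3
    size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.size_factors is not None:
            if len(self.size_factors) != self.n_samples:
                raise ValueError(
                    f"need {self.n_samples} size factors, got {len(self.size_factors)}"
                )
            if any(s <= 0 for s in self.size_factors):
                raise ValueError("size factors must be > 0")

    @property
    def n_samples(self) -> int:
        return 2 * 2 * self.n_reps

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{g}_{c}_r{r + 1}",
                "genotype": g,
                "condition": c,
                "replicate": r + 1,
            }
            for g in GENOTYPES
            for c in CONDITIONS
            for r in range(self.n_reps)
        ]
        return pd.DataFrame(rows)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with gene lengths and sample metadata.

    ``samples`` is a DataFrame with columns sample_id, genotype, condition,
    replicate; column order of ``counts`` follows ``samples``.
    """

    genes: list[str]
    lengths_bp: np.ndarray
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths_bp = np.asarray(self.lengths_bp, dtype=int)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        trip = self.samples[["genotype", "condition", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("duplicate (genotype, condition, replicate) triples")

    def sample_mask(self, genotype: str | None = None, condition: str | None = None) -> np.ndarray:
        m = np.ones(len(self.samples), dtype=bool)
        if genotype is not None:
            m &= (self.samples["genotype"] == genotype).to_numpy()
        if condition is not None:
            m &= (self.samples["condition"] == condition).to_numpy()
        return m

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples["sample_id"].tolist())
        df.insert(0, "length_bp", self.lengths_bp)
        df.insert(0, "gene_id", self.genes)
        return df


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha  # NB shape; p = n / (n + mu)
    return rng.negative_binomial(n, n / (n + mu))


def simulate_counts(specs: list[SimGeneSpec], design: SimDesign) -> CountMatrix:
    """Draw a seeded NB count matrix for ``specs`` under ``design``.

    The mean for gene g in sample s is
    ``size_factor(s) * base_mean(g) * induction(genotype(s), g)**[condition(s) == minusFe]``.
    Identical arguments give bit-identical matrices; each gene's stream is
    keyed by (design.seed, gene index).
    """
    if not specs:
        raise ValueError("no gene specs given")
    samples = design.sample_table()
    sf = (
        np.ones(design.n_samples)
        if design.size_factors is None
        else np.asarray(design.size_factors, dtype=float)
    )
    is_minus = (samples["condition"] == "minusFe").to_numpy()
    genotype = samples["genotype"].to_numpy()

    counts = np.empty((len(specs), design.n_samples), dtype=np.int64)
    for gi, spec in enumerate(specs):
        induction = np.where(
            genotype == "wildtype", spec.induction_wt, spec.induction_clf
        )
        mu = sf * spec.base_mean * induction**is_minus
        rng = np.random.default_rng([design.seed, gi])
        counts[gi] = _nb_draw(rng, mu, spec.dispersion)

    return CountMatrix(
        genes=[s.gene_id for s in specs],
        lengths_bp=np.array([s.length_bp for s in specs]),
        samples=samples,
        counts=counts,
    )


def default_scenario(
    n_fit: int,
    n_pye: int,
    n_background: int,
    seed: int,
    *,
    n_reps: int = 3,
    dispersion: float = 0.05,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    perturb_size_factors: bool = False,
) -> tuple[list[SimGeneSpec], SimDesign]:
    """Build the default study scenario.

    FIT-set genes cycle through the three FIT effect pairs, PYE-set genes
    through the three PYE pairs, background genes have induction 1 in both
    genotypes. Base means are drawn log-uniformly from ``base_mean_range``;
    size factors are 1 unless ``perturb_size_factors`` adds a log-normal
    (sd 0.1) library-size perturbation.
    """
    if n_fit < 1 or n_pye < 1:
        raise ValueError("n_fit and n_pye must be >= 1")
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rng = np.random.default_rng([seed, 2**20])  # scenario stream, not a gene stream
    lo, hi = base_mean_range

    def draw_base_mean() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    specs: list[SimGeneSpec] = []
    for i in range(n_fit):
        wt, clf = FIT_INDUCTION_PAIRS[i % 3]
        specs.append(
            SimGeneSpec(
                gene_id=f"FIT{i + 1:04d}",
                base_mean=draw_base_mean(),
                induction_wt=wt,
                induction_clf=clf,
                dispersion=dispersion,
                set_label="FIT",
            )
        )
    for i in range(n_pye):
        wt, clf = PYE_INDUCTION_PAIRS[i % 3]
        specs.append(
            SimGeneSpec(
                gene_id=f"PYE{i + 1:04d}",
                base_mean=draw_base_mean(),
                induction_wt=wt,
                induction_clf=clf,
                dispersion=dispersion,
                set_label="PYE",
            )
        )
    for i in range(n_background):
        specs.append(
            SimGeneSpec(
                gene_id=f"BG{i + 1:05d}",
                base_mean=draw_base_mean(),
                dispersion=dispersion,
                set_label="background",
            )
        )

    size_factors = None
    if perturb_size_factors:
        size_factors = tuple(np.exp(rng.normal(0.0, 0.1, size=2 * 2 * n_reps)))
    design = SimDesign(n_reps=n_reps, size_factors=size_factors, seed=seed)
    return specs, design


def gene_sets_from_specs(specs: list[SimGeneSpec]) -> dict[str, list[str]]:
    """Named gene sets (FIT / PYE / background) read off the spec labels."""
    sets: dict[str, list[str]] = {}
    for s in specs:
        sets.setdefault(s.set_label, []).append(s.gene_id)
    return sets
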
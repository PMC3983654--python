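"""Mutation-selection model for coding substitutions (dN/dS-style).

The model describes the observed counts of coding substitutions, broken
down by the 12 strand-specific single-nucleotide substitution types s and
the consequence class c in {synonymous, missense, nonsense}, as independent
Poisson variables

    n[s][c] ~ Poisson(r_s * L[s][c] * omega_c),   omega_syn = 1,

where L[s][c] is the mutational *opportunity* — the number of coding
positions at which a substitution of type s produces consequence c,
computed from the CDS sequences — r_s a per-type mutation rate, and
omega_mis / omega_non selection coefficients analogous to dN/dS.
Separating the 12 rates from the two selection parameters removes the
confounding of sequence composition and per-type rate differences from the
selection estimates.

Maximisation is by coordinate ascent with closed-form updates (for fixed
omega, r_hat_s = n_s. / sum_c L[s][c] omega_c, and symmetrically for
omega), which is globally convergent for this bilinear Poisson likelihood.
Deviations from neutrality (omega = 1) are tested by likelihood-ratio
tests against chi-square with one degree of freedom.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .annotate import GeneIndex, _cds_offset, _cds_sequence  # noqa: F401
from .types import Consequence, GeneInterval, MutationRecord

__all__ = [
    "SUBSTITUTION_TYPES",
    "CONSEQUENCE_CLASSES",
    "OpportunityMatrix",
    "build_opportunity_matrix",
    "count_type_consequences",
    "SelectionModel",
    "SelectionResults",
    "fit_selection_model",
    "lrt_neutrality",
    "simulate_counts",
    "random_cds",
]

_BASES = "ACGT"
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in _BASES for a in _BASES if a != r
)  # 12 strand-specific types, coding-strand orientation
CONSEQUENCE_CLASSES = ("synonymous", "missense", "nonsense")

_TYPE_INDEX = {t: i for i, t in enumerate(SUBSTITUTION_TYPES)}
_STOPS = {"TAA", "TAG", "TGA"}


def _codon_effects() -> dict[str, list[tuple[int, int]]]:
    """Per sense codon: the 9 (type index, consequence index) contributions."""
    table: dict[str, list[tuple[int, int]]] = {}
    for codon in ("".join(c) for c in itertools.product(_BASES, repeat=3)):
        if codon in _STOPS:
            continue
        ref_aa = str(Seq(codon).translate())
        effects = []
        for pos in range(3):
            ref = codon[pos]
            for alt in _BASES:
                if alt == ref:
                    continue
                alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                alt_aa = str(Seq(alt_codon).translate())
                if alt_aa == "*":
                    c = 2
                elif alt_aa == ref_aa:
                    c = 0
                else:
                    c = 1
                effects.append((_TYPE_INDEX[f"{ref}>{alt}"], c))
        table[codon] = effects
    return table


_CODON_EFFECTS = _codon_effects()


@dataclass
class OpportunityMatrix:
    """Coding-position counts L[s][c] per substitution type and consequence."""

    L: np.ndarray  # shape (12, 3), float

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (12, 3):
            raise ValueError(f"opportunity matrix must be 12x3, got {self.L.shape}")
        if (self.L < 0).any():
            raise ValueError("opportunity counts must be non-negative")

    @property
    def total_sites(self) -> float:
        """Sum of all opportunities: 3 x number of coding positions counted."""
        return float(self.L.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.L, index=list(SUBSTITUTION_TYPES), columns=list(CONSEQUENCE_CLASSES)
        )


def build_opportunity_matrix(cds_sequences: Iterable[str]) -> OpportunityMatrix:
    """Enumerate all single-base changes over the supplied CDS sequences.

    Each sequence must be in frame (length divisible by 3); a single
    trailing stop codon is allowed and skipped, an internal stop is an
    error.  Every coding position contributes its three alternative bases,
    so the matrix total is 3 x (number of sense-codon positions).
    """
    L = np.zeros((12, 3))
    for seq in cds_sequences:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"CDS length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        for i, codon in enumerate(codons):
            if codon in _STOPS:
                raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
            if set(codon) - set(_BASES):
                raise ValueError(f"non-ACGT codon {codon!r}")
            for s, c in _CODON_EFFECTS[codon]:
                L[s, c] += 1
    return OpportunityMatrix(L)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODING_CONSEQUENCES = {
    Consequence.SYNONYMOUS: 0,
    Consequence.MISSENSE: 1,
    Consequence.NONSENSE: 2,
}


def count_type_consequences(
    catalog: Iterable[MutationRecord],
    gene_models: GeneIndex | Sequence[GeneInterval],
) -> np.ndarray:
    """Observed n[s][c] from an annotated catalog (CDS SNVs only).

    Substitution types are oriented on the coding strand of the gene the
    record was annotated against; splice/UTR/non-coding records are
    excluded (CDS-only model).
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    genes = index.by_id()
    n = np.zeros((12, 3))
    for r in catalog:
        if not r.is_snv or r.consequence not in _CODING_CONSEQUENCES:
            continue
        gene = genes.get(r.gene_id) if r.gene_id else None
        strand = gene.strand if gene is not None else "+"
        ref, alt = r.ref_allele, r.alt_allele
        if strand == "-":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        n[_TYPE_INDEX[f"{ref}>{alt}"], _CODING_CONSEQUENCES[r.consequence]] += 1
    return n


def _poisson_loglik(n: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood up to the n! constant; 0*log(0) treated as 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(mu), 0.0)
    if np.isnan(term).any() or np.isneginf(term[n > 0]).any():
        return -np.inf
    return float(term.sum() - mu.sum())


def _fit_profile(
    n: np.ndarray,
    L: np.ndarray,
    free: tuple[bool, bool],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float, float, float]:
    """Coordinate-ascent MLE; ``free`` flags whether (omega_mis, omega_non)
    are estimated (fixed at 1 otherwise).  Returns (r, w_mis, w_non, loglik)."""
    active = L.sum(axis=1) > 0
    omega = np.ones(3)
    r = np.zeros(12)
    denom0 = (L[active] @ omega)
    r[active] = n[active].sum(axis=1) / denom0
    loglik = _poisson_loglik(n[active], np.outer(r[active], omega) * L[active])
    for _ in range(max_iter):
        for c, is_free in ((1, free[0]), (2, free[1])):
            if not is_free:
                continue
            denom = float(r[active] @ L[active, c])
            omega[c] = n[active, c].sum() / denom if denom > 0 else 0.0
        denom = L[active] @ omega
        with np.errstate(divide="ignore", invalid="ignore"):
            r_new = np.where(denom > 0, n[active].sum(axis=1) / denom, 0.0)
        r[active] = r_new
        new_loglik = _poisson_loglik(n[active], np.outer(r[active], omega) * L[active])
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return r, float(omega[1]), float(omega[2]), loglik


class SelectionModel:
    """Mutation-selection model bound to observed counts and opportunities.

    Parameters
    ----------
    counts : (12, 3) array
        Observed mutations per substitution type x consequence class
        (rows ordered as ``SUBSTITUTION_TYPES``, columns as
        ``CONSEQUENCE_CLASSES``).
    opportunity : OpportunityMatrix or (12, 3) array
        Coding-site opportunities from :func:`build_opportunity_matrix`.
    """

    def __init__(self, counts: np.ndarray, opportunity: OpportunityMatrix | np.ndarray):
        if not isinstance(opportunity, OpportunityMatrix):
            opportunity = OpportunityMatrix(np.asarray(opportunity))
        self.opportunity = opportunity
        self.counts = np.asarray(counts, dtype=float)
        if self.counts.shape != (12, 3):
            raise ValueError(f"counts must be 12x3, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("at least one observed mutation is required")
        L = self.opportunity.L
        if ((self.counts > 0) & (L == 0)).any():
            raise ValueError("observed mutations at cells with zero opportunity")
        dead = L.sum(axis=1) == 0
        if dead.any():
            names = [SUBSTITUTION_TYPES[i] for i in np.flatnonzero(dead)]
            warnings.warn(
                f"substitution types with zero opportunity excluded from fit: {names}",
                stacklevel=2,
            )
        for c, name in enumerate(CONSEQUENCE_CLASSES):
            if self.counts[:, c].sum() > 0 and L[:, c].sum() == 0:
                raise ValueError(
                    f"all-zero opportunity for consequence class {name!r} "
                    "with observed mutations"
                )

    @classmethod
    def from_catalog(
        cls,
        catalog: Iterable[MutationRecord],
        gene_models: GeneIndex | Sequence[GeneInterval],
        genome: Mapping[str, str],
    ) -> "SelectionModel":
        """Build counts and opportunities from an annotated catalog.

        The opportunity matrix is computed over the CDS of every supplied
        gene model (coding strand).
        """
        index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
        cds_seqs = [
            _cds_sequence(g, genome) for g in index.genes if g.cds_start is not None
        ]
        L = build_opportunity_matrix(cds_seqs)
        n = count_type_consequences(catalog, index)
        return cls(n, L)

    def fit(self, tol: float = 1e-10, max_iter: int = 10_000) -> "SelectionResults":
        """Maximum-likelihood fit of the full and both constrained models."""
        n, L = self.counts, self.opportunity.L
        r, w_mis, w_non, ll_full = _fit_profile(n, L, (True, True), tol, max_iter)
        _, _, _, ll_null_mis = _fit_profile(n, L, (False, True), tol, max_iter)
        _, _, _, ll_null_non = _fit_profile(n, L, (True, False), tol, max_iter)
        return SelectionResults(
            model=self,
            rates=pd.Series(r, index=list(SUBSTITUTION_TYPES), name="rate"),
            omega_mis=w_mis,
            omega_non=w_non,
            loglik_full=ll_full,
            loglik_null_mis=ll_null_mis,
            loglik_null_non=ll_null_non,
        )


@dataclass
class SelectionResults:
    """MLEs, log-likelihoods and neutrality tests from a SelectionModel fit."""

    model: SelectionModel
    rates: pd.Series
    omega_mis: float
    omega_non: float
    loglik_full: float
    loglik_null_mis: float
    loglik_null_non: float

    @property
    def lrt_stat_mis(self) -> float:
        return max(0.0, 2.0 * (self.loglik_full - self.loglik_null_mis))

    @property
    def lrt_stat_non(self) -> float:
        return max(0.0, 2.0 * (self.loglik_full - self.loglik_null_non))

    @property
    def p_mis(self) -> float:
        """LRT p-value for omega_mis = 1 (chi-square, 1 df)."""
        return float(stats.chi2.sf(self.lrt_stat_mis, df=1))

    @property
    def p_non(self) -> float:
        return float(stats.chi2.sf(self.lrt_stat_non, df=1))

    def summary(self) -> str:
        lines = [
            "Mutation-selection model (Poisson ML, 12 rates + 2 selection params)",
            f"  observed mutations: {int(self.model.counts.sum())}",
            f"  opportunity sites:  {self.model.opportunity.total_sites:.0f}",
            f"  log-likelihood (full): {self.loglik_full:.4f}",
            f"  omega_mis (dM/dS):  {self.omega_mis:8.4f}   LRT p = {self.p_mis:.4g}",
            f"  omega_non (dNS/dS): {self.omega_non:8.4f}   LRT p = {self.p_non:.4g}",
            "  per-type rates (per opportunity site):",
        ]
        for t, r in self.rates.items():
            lines.append(f"    {t}: {r:.6g}")
        return "\n".join(lines)


def fit_selection_model(
    observed_counts: np.ndarray, opportunity: OpportunityMatrix | np.ndarray
) -> SelectionResults:
    """Convenience wrapper: ``SelectionModel(n, L).fit()``."""
    return SelectionModel(observed_counts, opportunity).fit()


def lrt_neutrality(fit: SelectionResults) -> tuple[float, float]:
    """(p_mis, p_non) likelihood-ratio p-values against omega = 1."""
    if fit.loglik_full + 1e-6 < max(fit.loglik_null_mis, fit.loglik_null_non):
        raise ValueError("constrained fit exceeds full fit; fits are not nested")
    return fit.p_mis, fit.p_non


def simulate_counts(
    opportunity: OpportunityMatrix | np.ndarray,
    rates: np.ndarray | float,
    omega_mis: float,
    omega_non: float,
    rng: np.random.Generator,
    total: int | None = None,
) -> np.ndarray:
    """Draw n[s][c] from the model.

    With ``total`` set, exactly that many mutations are drawn
    (multinomially over cells, i.e. Poisson conditioned on the total);
    otherwise each cell is an independent Poisson draw.
    """
    L = opportunity.L if isinstance(opportunity, OpportunityMatrix) else np.asarray(opportunity)
    r = np.broadcast_to(np.asarray(rates, dtype=float), (12,)).reshape(12, 1)
    mu = r * L * np.array([1.0, omega_mis, omega_non])
    if total is None:
        return rng.poisson(mu).astype(float)
    p = mu.ravel() / mu.sum()
    return rng.multinomial(total, p).reshape(12, 3).astype(float)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random in-frame CDS of sense codons (no stops), for simulations."""
    sense = sorted(set(_CODON_EFFECTS))
    return "".join(rng.choice(sense) for _ in range(n_codons))
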
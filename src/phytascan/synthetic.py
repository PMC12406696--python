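"""Synthetic data generators with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: background proteomes
with planted phytase homologs at controlled divergence (intact or with
deliberately broken catalytic motifs), per-sample gene/marker count tables,
community matrices assembled under neutral versus strongly selective
regimes, Michaelis–Menten rate data, and synthetic stand-in sequences for
the reference catalog. All generators are deterministic given their seed,
and each planted object is recorded in a truth table sufficient to score
search and screening exactly.

The reference stand-ins deserve emphasis: real catalogued protein sequences
are not redistributed with the package, so
:func:`synthetic_reference_sequences` builds, for each catalogued
representative, a random-background sequence carrying the representative's
concrete motifs at their catalogued anchor positions, plus mutated copies
(well above the clade identity threshold) standing in for the catalogued
homolog accessions. These synthetic sequences reproduce the catalog's clade
structure and motif anchors without containing any real sequence data.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._aminoacids import ALPHABET, BACKGROUND
from .abundance import DEFAULT_MARKER_GENES
from .biochem import mm_rate
from .catalog import ReferenceEnzyme, load_catalog
from .ecology import CommunityMatrix
from .screen import MotifPattern, motif_for_clade

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "random_proteome",
    "synthetic_reference_sequences",
    "attach_synthetic_sequences",
    "expanded_reference_set",
    "plant_homologs",
    "simulate_sample_counts",
    "simulate_community_assembly",
    "simulate_kinetics_data",
]

# Fixed internal seed for the reference stand-ins: they are a vendored
# fixture shared by every analysis, not a per-run simulation condition.
_REFERENCE_FIXTURE_SEED = 28_031_858


def _sub_seed(seed: int, *tokens: str | int) -> list[int]:
    """Derive a seed sequence from a base seed and string/int tokens."""
    out: list[int] = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, int):
            out.append(t & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
    return out


def random_proteome(
    n: int,
    length_distribution: tuple[float, float] = (300.0, 60.0),
    seed: int = 0,
    id_prefix: str = "bg",
) -> dict[str, str]:
    """``n`` i.i.d. background proteins with normal length distribution.

    Residues are drawn from the package's background composition; lengths
    are floored at 30 residues.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mean, sd = length_distribution
    rng = np.random.default_rng(_sub_seed(seed, "proteome"))
    out: dict[str, str] = {}
    for i in range(n):
        length = max(30, int(round(rng.normal(mean, sd))))
        idx = rng.choice(len(ALPHABET), size=length, p=BACKGROUND)
        out[f"{id_prefix}_{i + 1:05d}"] = "".join(ALPHABET[j] for j in idx)
    return out


def synthetic_reference_sequences(
    catalog: Sequence[ReferenceEnzyme] | None = None,
    member_identity: float = 0.8,
    seed: int = _REFERENCE_FIXTURE_SEED,
) -> dict[str, str]:
    """Synthetic stand-in sequences for the reference catalog (see module docs).

    Returns accession → sequence for every representative and catalogued
    homolog. Representative stand-ins carry the concrete motifs at the
    catalogued anchors; homolog stand-ins are motif-preserving mutated
    copies at ``member_identity`` to their representative.
    """
    if catalog is None:
        catalog = load_catalog()
    seqs: dict[str, str] = {}
    for enz in catalog:
        rng = np.random.default_rng(_sub_seed(seed, enz.accession))
        length = (max(end for _, _, end in enz.motifs) if enz.motifs else 240) + 60
        arr = [ALPHABET[j] for j in rng.choice(len(ALPHABET), size=length, p=BACKGROUND)]
        for pattern, start, _end in enz.motifs:
            arr[start - 1 : start - 1 + len(pattern)] = list(pattern)
        rep = "".join(arr)
        seqs[enz.accession] = rep
        protected = _motif_columns(enz)
        for hom in enz.homologs:
            hrng = np.random.default_rng(_sub_seed(seed, enz.accession, hom))
            seqs[hom] = _mutate(rep, member_identity, protected, hrng)
    return seqs


def attach_synthetic_sequences(
    catalog: Sequence[ReferenceEnzyme] | None = None,
    member_identity: float = 0.8,
) -> list[ReferenceEnzyme]:
    """The bundled catalog with synthetic stand-in sequences attached."""
    if catalog is None:
        catalog = load_catalog()
    seqs = synthetic_reference_sequences(catalog, member_identity)
    return [e.with_sequence(seqs[e.accession]) for e in catalog]


def expanded_reference_set(
    catalog: Sequence[ReferenceEnzyme] | None = None,
    member_identity: float = 0.8,
) -> list[ReferenceEnzyme]:
    """Representatives plus homolog members as sequence-bearing enzymes.

    Homolog entries inherit their representative's family, clade label and
    motif anchors (stand-in mutations never touch motif columns), giving a
    validated-set-sized input for clade clustering.
    """
    if catalog is None:
        catalog = load_catalog()
    seqs = synthetic_reference_sequences(catalog, member_identity)
    out: list[ReferenceEnzyme] = []
    for enz in catalog:
        out.append(enz.with_sequence(seqs[enz.accession]))
        for hom in enz.homologs:
            out.append(
                ReferenceEnzyme(
                    accession=hom,
                    family=enz.family,
                    clade_label=enz.clade_label,
                    organism=enz.organism,
                    sequence=seqs[hom],
                    motifs=enz.motifs,
                )
            )
    return out


def _motif_columns(enzyme: ReferenceEnzyme) -> set[int]:
    """0-based sequence columns covered by the enzyme's motif anchors."""
    cols: set[int] = set()
    for _pattern, start, end in enzyme.motifs:
        cols.update(range(start - 1, end))
    return cols


def _mutate(
    seq: str,
    target_identity: float,
    protected: set[int],
    rng: np.random.Generator,
) -> str:
    """Point-substitute down to ``target_identity``, avoiding protected columns."""
    length = len(seq)
    n_sub = int(round((1.0 - target_identity) * length))
    available = sorted(set(range(length)) - protected)
    if n_sub > len(available):
        minimum = 1.0 - len(available) / length
        raise ValueError(
            f"target identity {target_identity} too low to preserve motifs; "
            f"minimum is {minimum:.3f}"
        )
    arr = list(seq)
    for pos in rng.choice(len(available), size=n_sub, replace=False):
        col = available[int(pos)]
        choices = [a for a in ALPHABET if a != arr[col]]
        arr[col] = choices[int(rng.integers(len(choices)))]
    return "".join(arr)


def _find_in_window(seq: str, pattern: MotifPattern) -> int | None:
    """0-based match start of a motif near its anchor, or None (nearest-first)."""
    start0 = pattern.anchor[0] - 1
    for delta in sorted(range(-pattern.tolerance_window, pattern.tolerance_window + 1), key=abs):
        if pattern.matches_at(seq, start0 + delta) is not None:
            return start0 + delta
    return None


def _break_motif(arr: list[str], pattern: MotifPattern, rng: np.random.Generator) -> None:
    """Mutate residues until no alternate of the motif matches near its anchor."""
    for _ in range(100):
        hit = _find_in_window("".join(arr), pattern)
        if hit is None:
            return
        max_len = max(len(alt) for alt in pattern.alternates)
        # try offsets from most constrained token outward
        offsets = sorted(
            range(max_len),
            key=lambda j: len(
                set().union(*(alt[j] for alt in pattern.alternates if j < len(alt)))
            ),
        )
        for j in offsets:
            union = set().union(*(alt[j] for alt in pattern.alternates if j < len(alt)))
            choices = [a for a in ALPHABET if a not in union and a != arr[hit + j]]
            if choices and hit + j < len(arr):
                arr[hit + j] = choices[int(rng.integers(len(choices)))]
                break
        else:  # pragma: no cover - patterns always have a constrained token
            raise RuntimeError(f"cannot break motif {pattern.source!r}")
    raise RuntimeError(f"motif {pattern.source!r} still matches after 100 attempts")


def plant_homologs(
    background: Mapping[str, str],
    representative: ReferenceEnzyme,
    copies: int,
    target_identity: float = 0.6,
    motif_intact: bool = True,
    seed: int = 0,
    taxon_class: str = "Gammaproteobacteria",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant mutated copies of a clade representative into a background proteome.

    Substitutions avoid motif columns when ``motif_intact``; otherwise every
    motif of the clade is additionally disrupted at a constrained (fixed)
    residue so that the copy fails screening. Returns the combined protein
    set and a truth table (seq_id, clade, intact, taxon_class, identities).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if not representative.sequence:
        raise ValueError(f"representative {representative.accession} has no sequence")
    rep = representative.sequence
    patterns = motif_for_clade(representative)
    protected = _motif_columns(representative)
    proteins = dict(background)
    rows = []
    tag = "intact" if motif_intact else "broken"
    prefix = f"planted_{representative.clade_id}_{tag}"
    rng = np.random.default_rng(_sub_seed(seed, prefix))
    for c in range(copies):
        mutated = _mutate(rep, target_identity, protected, rng)
        arr = list(mutated)
        if not motif_intact:
            for pattern in patterns:
                _break_motif(arr, pattern, rng)
        seq = "".join(arr)
        seq_id = f"{prefix}_{c + 1:03d}"
        if seq_id in proteins:
            raise ValueError(f"id collision with background: {seq_id}")
        proteins[seq_id] = seq
        realized = sum(a == b for a, b in zip(seq, rep)) / len(rep)
        rows.append(
            {
                "seq_id": seq_id,
                "clade": representative.clade_id,
                "intact": motif_intact,
                "taxon_class": taxon_class,
                "target_identity": target_identity,
                "realized_identity": realized,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "seq_id", "clade", "intact", "taxon_class",
            "target_identity", "realized_identity",
        ],
    )
    return proteins, truth


def simulate_sample_counts(
    true_abundance: pd.DataFrame,
    depths: Mapping[str, float] | pd.Series | None = None,
    marker_mean: float = 100.0,
    marker_genes: Sequence[str] = DEFAULT_MARKER_GENES,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson gene/marker count tables around known relative abundances.

    ``true_abundance`` is samples × genes of marker-normalized relative
    abundance (the ground truth the normalization step should recover);
    ``depths`` is a per-sample sequencing-depth factor (default 1.0).
    Expected marker count is ``depth × marker_mean`` for each of the marker
    genes, and expected gene count is ``depth × marker_mean × abundance``.
    """
    samples = list(true_abundance.index)
    if depths is None:
        depths = pd.Series(1.0, index=samples)
    depths = pd.Series(depths).reindex(samples)
    if depths.isna().any() or (depths <= 0).any():
        raise ValueError("every sample needs a positive depth factor")
    rng = np.random.default_rng(_sub_seed(seed, "counts"))
    lam_genes = true_abundance.mul(depths * marker_mean, axis=0)
    gene_counts = pd.DataFrame(
        rng.poisson(lam_genes.values.astype(float)),
        index=samples, columns=true_abundance.columns,
    )
    lam_markers = np.outer(depths.values * marker_mean, np.ones(len(marker_genes)))
    marker_counts = pd.DataFrame(
        rng.poisson(lam_markers), index=samples, columns=list(marker_genes)
    )
    return gene_counts.astype(float), marker_counts.astype(float)


def simulate_community_assembly(
    mode: str,
    n_samples: int,
    n_taxa: int = 120,
    seed: int = 0,
    depth: int = 2000,
    metacommunity_sigma: float = 1.0,
    drift_sigma: float = 1.5,
    selection_noise: float = 0.05,
    core_fraction: float = 1.0 / 3.0,
) -> CommunityMatrix:
    """Sample × taxon count matrices under neutral or selective assembly.

    Neutral mode draws each sample multinomially from a shared lognormal
    metacommunity whose per-sample relative abundances drift by a lognormal
    factor (``drift_sigma``) — taxon identities carry no deterministic
    signal. Selection mode restricts all samples to one fixed core
    composition (a ``core_fraction`` subset of the taxon pool) perturbed
    only by ``selection_noise``, emulating strong environmental filtering.
    """
    if n_samples < 6:
        raise ValueError("need at least 6 samples")
    if mode not in ("neutral", "selection"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    rng = np.random.default_rng(_sub_seed(seed, "assembly", mode))
    meta = rng.lognormal(0.0, metacommunity_sigma, n_taxa)
    meta /= meta.sum()
    rows = np.zeros((n_samples, n_taxa), dtype=float)
    if mode == "selection":
        core = rng.choice(n_taxa, size=max(3, int(round(core_fraction * n_taxa))), replace=False)
        target = np.zeros(n_taxa)
        target[core] = meta[core]
        target /= target.sum()
    for i in range(n_samples):
        if mode == "neutral":
            p = meta * rng.lognormal(0.0, drift_sigma, n_taxa)
        else:
            p = target * rng.lognormal(0.0, selection_noise, n_taxa)
        p /= p.sum()
        rows[i] = rng.multinomial(depth, p)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    taxa = [f"T{j + 1:03d}" for j in range(n_taxa)]
    frame = pd.DataFrame(rows, index=samples, columns=taxa)
    return CommunityMatrix(abundance=frame, groups=pd.Series(mode, index=samples))


def simulate_kinetics_data(
    km: float,
    vmax: float,
    s_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Michaelis–Menten rate observations, optionally with Gaussian noise.

    Noise is truncated just above zero so reciprocal fits stay defined.
    Warns when the substrate grid does not bracket Km (an ill-conditioned
    design: Km is then poorly identified).
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    s = np.asarray(list(s_grid), dtype=float)
    if (s <= 0).any():
        raise ValueError("substrate grid must be positive")
    v = mm_rate(s, km, vmax)
    if noise_sd > 0:
        rng = np.random.default_rng(_sub_seed(seed if seed is not None else 0, "kinetics"))
        v = np.maximum(v + rng.normal(0.0, noise_sd, v.shape), 1e-9)
    if s.min() > 2.0 * km:
        warnings.warn(
            "substrate grid lies entirely above 2×Km: the design is "
            "ill-conditioned for Km estimation",
            stacklevel=2,
        )
    return pd.DataFrame({"S_mM": s, "v": v})


@dataclass
class SyntheticSpec:
    """Declarative description of a full synthetic dataset."""

    seed: int
    n_background: int = 1000
    length_distribution: tuple[float, float] = (300.0, 60.0)
    #: (clade_id, copies, target_identity, motif_intact, taxon_class)
    planted: list[tuple[str, int, float, bool, str]] = field(default_factory=list)
    assembly_mode: str = "neutral"
    n_samples: int = 12
    n_taxa: int = 120

    def __post_init__(self) -> None:
        for clade_id, copies, ident, _intact, _cls in self.planted:
            if copies < 0:
                raise ValueError(f"{clade_id}: copies must be non-negative")
            if not 0 < ident <= 1:
                raise ValueError(f"{clade_id}: target identity must be in (0, 1]")


def generate_dataset(spec: SyntheticSpec):
    """Materialize a SyntheticSpec: proteins + truth table + community matrix."""
    catalog = attach_synthetic_sequences()
    by_clade = {e.clade_id: e for e in catalog}
    proteins = random_proteome(
        spec.n_background, spec.length_distribution, seed=spec.seed
    )
    truths = []
    for clade_id, copies, ident, intact, taxon_class in spec.planted:
        if clade_id not in by_clade:
            raise KeyError(f"unknown clade {clade_id!r}")
        proteins, truth = plant_homologs(
            proteins, by_clade[clade_id], copies, ident, intact,
            seed=spec.seed, taxon_class=taxon_class,
        )
        truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=[
                "seq_id", "clade", "intact", "taxon_class",
                "target_identity", "realized_identity",
            ]
        )
    )
    community = simulate_community_assembly(
        spec.assembly_mode, spec.n_samples, spec.n_taxa, seed=spec.seed
    )
    return proteins, truth, community
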
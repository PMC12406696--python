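"""Reference catalog of validated phytate-hydrolysing enzymes.

The bundled catalog lists biochemically or structurally characterized
phytases of the four canonical families — β-propeller phytases (BPP),
histidine acid phytases (HAP), cysteine phytases (CP) and purple acid
phytases (PAP) — each clade named after the prefix of its representative
accession, together with the conserved catalytic / substrate-binding motifs
of each representative and their 1-based anchor positions. Homologous
accessions sharing >28% sequence identity with a representative belong to
the same clade.

Reference protein sequences are not redistributed with the package: they can
be fetched from NCBI with :func:`fetch_sequences`, or synthetic stand-ins
embedding the catalogued motif anchors can be generated with
:func:`phytascan.synthetic.synthetic_reference_sequences` for offline use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._pairwise import identity_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "FAMILY_MOTIF_PATTERNS",
    "ReferenceEnzyme",
    "CladeDefinition",
    "CatalogError",
    "load_catalog",
    "load_alkaline_phosphatase_catalog",
    "pairwise_identity",
    "cluster_into_clades",
    "select_representative",
    "fetch_sequences",
]

FAMILIES = ("BPP", "HAP", "CP", "PAP")

#: Family-level consensus motifs. ``X`` matches any residue, ``[D/E]`` a set,
#: ``HD/HAE`` whole-motif alternates. Individual representatives may deviate;
#: their concrete motifs (below) are accepted as alternates during screening.
FAMILY_MOTIF_PATTERNS: dict[str, tuple[str, ...]] = {
    "BPP": ("YG", "EGXXXD", "DXEG", "DG"),
    "HAP": ("RHGXRXP", "HD/HAE"),
    "CP": ("DH", "HCXXGXGRT"),
    "PAP": ("GDXG", "GNH[D/E]", "VXXXH", "GHXH"),
}


class CatalogError(ValueError):
    """Malformed or inconsistent catalog input."""


@dataclass(frozen=True)
class ReferenceEnzyme:
    """One validated enzyme: a clade representative or a catalogued homolog."""

    accession: str
    family: str
    clade_label: str
    organism: str = ""
    sequence: str | None = None
    #: concrete motifs of this sequence: (pattern, start, end), 1-based inclusive.
    motifs: tuple[tuple[str, int, int], ...] = ()
    #: homolog accessions grouped with this representative (>28% identity).
    homologs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("ALP",):
            raise CatalogError(f"{self.accession}: unknown family {self.family!r}")
        for pat, start, end in self.motifs:
            if not (1 <= start <= end):
                raise CatalogError(
                    f"{self.accession}: motif {pat!r} has invalid anchor {start}-{end}"
                )
            if end - start + 1 != len(pat):
                raise CatalogError(
                    f"{self.accession}: motif {pat!r} length does not match anchor "
                    f"{start}-{end}"
                )

    @property
    def clade_id(self) -> str:
        """Family-qualified clade name (clade labels repeat across families)."""
        return f"{self.family}_{self.clade_label}"

    def with_sequence(self, sequence: str) -> "ReferenceEnzyme":
        return replace(self, sequence=sequence)


@dataclass
class CladeDefinition:
    """A clade: representative plus members above the identity threshold."""

    clade_label: str
    family: str
    representative: str
    members: set[str] = field(default_factory=set)
    identity_threshold: float = 0.28

    def __post_init__(self) -> None:
        self.members.add(self.representative)

    @property
    def clade_id(self) -> str:
        return f"{self.family}_{self.clade_label}"


# Bundled catalog in the same columnar format accepted from disk:
# accession, family, clade, organism, motifs ("pattern;start;end|..."), homologs.
_BUILTIN_CATALOG_TSV = """\
accession\tfamily\tclade\torganism\tmotifs\thomologs
ABL86758\tBPP\tABL\tBacillus subtilis ARRMK33\tYG;159;160|EGMAAD;211;216|DIEG;258;261|DG;314;315\tAAC31775.1,AAC38573.1,AAM74021.1,ABP02074.1,ACZ57955.1,AEC13691.1,AFD29183.1,AVV65759.1,CAM58513.1,CRL66425.1,O31097,O66037,P42094,ABQ66899.1,CQR59166.1,MBO9525759.1
AQX17444\tBPP\tAQX\tPseudomonas sp. FB15\tYG;418;419|EGCVAD;468;473|DVEG;514;517|DG;571;572\tAAN55555.1,ADZ99372.1,ADZ99940.1,AEQ29499.1,AHM26864.1,AJF36073.1,UNF21334.1
ACJ35482\tBPP\tACJ\tPedobacter nyackensis MJ11\tMG;170;171|ESIAVD;229;234|DNEG;274;277|DG;329;330\t-
QJA16365\tBPP\tQJA\tArthrobotrys oligospora ATCC 24927\tYG;529;530|EGCVVD;583;588|DVEG;632;635|DG;691;692\t-
AAA32705\tHAP\tAAA\tAspergillus niger\tRHGARYP;81;87|HD;361;362\tAAB96872.1,AAN10115.1,AAU93517.1,CAC48195.1,D4ANW6,O00085,O00093,O00100,O00107,P34753,Q0CLV1,Q9C1T1
ABG88857\tHAP\tABG\tAspergillus niger WP1\tRHGERYP;65;71|HD;321;322\t2GFI_A,AAA02934.1,ABU49229.1,ADF49635.1,P34755,ABN04184.1
WP_057099050\tHAP\t050\tBacteroides thetaiotaomicron\tRHGARFP;58;64|HAE;323;325\t-
ACJ51391\tHAP\tACJ\tBifidobacterium longum\tRHGSRGL;74;80|HAE;429;431\t-
WP_027265797\tHAP\t797\tLegionella pneumophila\tRHGDRTP;33;39|HD;280;281\t-
WP_198495896\tHAP\t896\tmetagenome\tRHGNRTP;45;51|HD;293;294\tJGI1357J11328_100303543
AAM23271\tHAP\tAAM\tKlebsiella sp. ASR1\tRHGIRPP;40;46|HD;306;307\tAAL59319.1,ABW76125.1
AAR89622\tHAP\tAAR\tCitrobacter freundii\tRHGVRAP;38;44|HD;324;325\tAAR87658.1,AAS45884.1,ABI95370.1,ABI98040.1,ABX75421.1,ABX80238.1,ACB54699.1,AFG25721.1,BAQ94585.1,QPN96261.1,P07102,WP_117343249.1,P19926,AIE90144.1
AAQ13669\tCP\tAAQ\tSelenomonas ruminantium JY35\tDH;223;224|HCEAGVGRT;251;259\tABA18187.1,ABC69358.4,ABC69359.4,ABC69361.2,ABC69367.2,ADG23212.1,ADG23213.1,CAE79111.1,WP_011590872.1
AWN00236\tCP\tAWN\tStreptacidiphilus melanogenes\tYF;240;241|HCTAGKDRT;268;276\t-
ACR23329\tPAP\tACR\tTriticum aestivum\tGDLG;193;196|GNHE;277;280|VAGWH;356;360|GHVH;396;399\tANG56539.1,ACR23326.1,ACR23333.1,ACR23335.1,AEG77017.1,ACR23327.1,ACR23331.1,AEG77016.1,ADG07931.1,AEA39182.1,ACR23328.1,ACR23332.1,ABP96799.1,AAX71115.1,AAN74650.1,ACD87745.1,ADM32493.1,ADM88044.1,ADI50286.1,AAK49438.1,AAE83899.1,AAX20028.1,AJK28063.1,WP_017329228.1
XP_004504591\tPAP\tXP\tCicer arietinum L.\tGDWG;52;55|GNHD;123;126|VVGHH;215;219|GHDH;252;255\tNP_001242830.2
"""

#: Alkaline phosphatases kept as an alternate, E-value-only catalog namespace
#: (no catalytic-motif screening is defined for them here).
_ALP_GENES = ("PafA", "Psip1", "PhoA", "PhoD", "PhoK", "PhoX")


def _parse_catalog_text(text: str) -> list[ReferenceEnzyme]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("catalog source is empty; returning empty catalog")
        return []
    header = lines[0].rstrip("\n").split("\t")
    required = ["accession", "family", "clade", "organism", "motifs", "homologs"]
    if header[: len(required)] != required:
        raise CatalogError(f"unexpected catalog header {header!r}; expected {required!r}")
    enzymes: list[ReferenceEnzyme] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise CatalogError(f"malformed catalog record (needs 6 columns): {ln!r}")
        acc, family, clade, organism, motif_field, homolog_field = fields[:6]
        if acc in seen:
            raise CatalogError(f"duplicate accession in catalog: {acc}")
        seen.add(acc)
        motifs: list[tuple[str, int, int]] = []
        if motif_field and motif_field != "-":
            for chunk in motif_field.split("|"):
                parts = chunk.split(";")
                if len(parts) != 3:
                    raise CatalogError(f"{acc}: malformed motif spec {chunk!r}")
                try:
                    motifs.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise CatalogError(f"{acc}: malformed motif anchor in {chunk!r}") from exc
        homologs = tuple(
            h.strip() for h in homolog_field.split(",") if h.strip() and h.strip() != "-"
        )
        enzymes.append(
            ReferenceEnzyme(
                accession=acc,
                family=family,
                clade_label=clade,
                organism=organism,
                motifs=tuple(motifs),
                homologs=homologs,
            )
        )
    return enzymes


def load_catalog(catalog_source: str | Path | None = None) -> list[ReferenceEnzyme]:
    """Load the reference catalog.

    Parameters
    ----------
    catalog_source
        Path to a columnar TSV (``accession family clade organism motifs
        homologs``), or ``None`` for the bundled catalog of validated
        phytases (4 BPP, 8 HAP, 2 CP and 2 PAP clade representatives with
        their homolog lists and motif anchors).
    """
    if catalog_source is None:
        return _parse_catalog_text(_BUILTIN_CATALOG_TSV)
    text = Path(catalog_source).read_text()
    return _parse_catalog_text(text)


def load_alkaline_phosphatase_catalog() -> list[ReferenceEnzyme]:
    """Alternate catalog namespace: alkaline phosphatases, searched by E-value only."""
    return [
        ReferenceEnzyme(accession=g, family="ALP", clade_label=g, organism="")
        for g in _ALP_GENES
    ]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Pairwise sequence identity in [0, 1].

    Identical residues over aligned columns of a global alignment (BLOSUM62,
    gap open 10 / extend 0.5); internal gap columns count, terminal overhangs
    do not. Symmetric up to alignment ties.
    """
    return identity_fraction(seq_a, seq_b)


def cluster_into_clades(
    enzymes: Sequence[ReferenceEnzyme],
    threshold: float = 0.28,
) -> list[CladeDefinition]:
    """Group enzymes of each family into clades by representative linkage.

    Sequences are processed in descending length order (ties keep input
    order); a sequence joins the existing clade whose seed it matches best
    with identity strictly above ``threshold``, otherwise it seeds a new
    clade. Clades therefore partition the input, and clustering is performed
    within families so clades never straddle family boundaries.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"identity threshold must be in (0, 1), got {threshold}")
    missing = [e.accession for e in enzymes if not e.sequence]
    if missing:
        raise ValueError(f"enzymes without sequences cannot be clustered: {missing}")

    clades: list[CladeDefinition] = []
    for family in dict.fromkeys(e.family for e in enzymes):
        fam = [e for e in enzymes if e.family == family]
        fam.sort(key=lambda e: -len(e.sequence))  # stable: input order breaks ties
        seeds: list[ReferenceEnzyme] = []
        fam_clades: list[CladeDefinition] = []
        for enz in fam:
            best_i, best_ident = -1, threshold
            for i, seed in enumerate(seeds):
                ident = identity_fraction(enz.sequence, seed.sequence)
                if ident > best_ident:
                    best_i, best_ident = i, ident
            if best_i >= 0:
                fam_clades[best_i].members.add(enz.accession)
            else:
                seeds.append(enz)
                fam_clades.append(
                    CladeDefinition(
                        clade_label=enz.clade_label or enz.accession,
                        family=family,
                        representative=enz.accession,
                        identity_threshold=threshold,
                    )
                )
        clades.extend(fam_clades)
    return clades


def select_representative(
    clade_members: Sequence[ReferenceEnzyme] | Sequence[str],
    scores: Mapping[str, float],
) -> str:
    """Pick the best-scoring member (ties broken lexicographically by accession)."""
    accessions = [
        m.accession if isinstance(m, ReferenceEnzyme) else m for m in clade_members
    ]
    if not accessions:
        raise ValueError("clade has no members")
    missing = [a for a in accessions if a not in scores]
    if missing:
        raise ValueError(f"scores missing for members: {missing}")
    return min(accessions, key=lambda a: (-scores[a], a))


def fetch_sequences(
    accessions: Iterable[str],
    email: str,
    *,
    batch_size: int = 50,
) -> dict[str, str]:
    """Fetch reference protein sequences from NCBI (requires network access).

    Thin Entrez helper for users who want the real catalogued sequences; the
    rest of the package works equally with synthetic stand-ins
    (:func:`phytascan.synthetic.synthetic_reference_sequences`).
    """
    from io import StringIO

    from Bio import Entrez, SeqIO

    Entrez.email = email
    accessions = list(accessions)
    out: dict[str, str] = {}
    for i in range(0, len(accessions), batch_size):
        chunk = accessions[i : i + batch_size]
        handle = Entrez.efetch(
            db="protein", id=",".join(chunk), rettype="fasta", retmode="text"
        )
        for rec in SeqIO.parse(StringIO(handle.read()), "fasta"):
            out[rec.id.split(".")[0]] = str(rec.seq)
    return out
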
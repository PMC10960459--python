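"""Canonical mitochondrial gene tokens and name normalization.

The animal mitochondrial genome carries 37 genes: 13 protein-coding genes,
2 rRNAs and 22 tRNAs.  Annotations in the wild use many spellings for the
same gene (COI vs cox1, 16S vs rrnL, tRNA-Leu(UUR) vs trnL2 ...); everything
entering the package is funnelled through :func:`normalize_gene_name`.
Unknown names raise rather than guess.
"""

from __future__ import annotations

PROTEIN_GENES = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
RRNA_GENES = ("rrnS", "rrnL")
TRNA_GENES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

#: The canonical 37-token alphabet, fixed order for reporting.
CANONICAL_GENES = PROTEIN_GENES + RRNA_GENES + TRNA_GENES
CANONICAL_SET = frozenset(CANONICAL_GENES)

# Single-letter amino-acid code -> tRNA token (leucine and serine are split
# by anticodon family and handled separately).
_AA_SINGLE = {
    "A": "trnA", "R": "trnR", "N": "trnN", "D": "trnD", "C": "trnC",
    "E": "trnE", "Q": "trnQ", "G": "trnG", "H": "trnH", "I": "trnI",
    "K": "trnK", "M": "trnM", "F": "trnF", "P": "trnP", "T": "trnT",
    "W": "trnW", "Y": "trnY", "V": "trnV",
}

_AA3 = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "glu": "trnE", "gln": "trnQ", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
}

# Synonym table (lower-cased lookup).  Editable by callers via
# register_synonym(); ships with the spellings seen in arthropod mitogenome
# records.
SYNONYMS: dict[str, str] = {
    # protein-coding genes
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cytochrome c oxidase subunit i": "cox1",
    "cytochrome c oxidase subunit ii": "cox2",
    "cytochrome c oxidase subunit iii": "cox3",
    "cytochrome c oxidase subunit 1": "cox1",
    "cytochrome c oxidase subunit 2": "cox2",
    "cytochrome c oxidase subunit 3": "cox3",
    "cob": "cob", "cytb": "cob", "cyt b": "cob", "cob/cytb": "cob",
    "cytochrome b": "cob", "cytochrome b apoenzyme": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4L", "nad5": "nad5", "nad6": "nad6",
    "nadh dehydrogenase subunit 1": "nad1",
    "nadh dehydrogenase subunit 2": "nad2",
    "nadh dehydrogenase subunit 3": "nad3",
    "nadh dehydrogenase subunit 4": "nad4",
    "nadh dehydrogenase subunit 4l": "nad4L",
    "nadh dehydrogenase subunit 5": "nad5",
    "nadh dehydrogenase subunit 6": "nad6",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "atp synthase f0 subunit 6": "atp6",
    "atp synthase f0 subunit 8": "atp8",
    # rRNAs
    "rrns": "rrnS", "rrnl": "rrnL",
    "12s": "rrnS", "16s": "rrnL",
    "12s rrna": "rrnS", "16s rrna": "rrnL",
    "12s ribosomal rna": "rrnS", "16s ribosomal rna": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "srrna": "rrnS", "lrrna": "rrnL",
    "small subunit ribosomal rna": "rrnS",
    "large subunit ribosomal rna": "rrnL",
}


def register_synonym(alias: str, canonical: str) -> None:
    """Add a user synonym (e.g. from a config file) to the lookup table."""
    if canonical not in CANONICAL_SET:
        raise ValueError(f"unknown canonical gene token: {canonical!r}")
    SYNONYMS[alias.strip().lower()] = canonical


def normalize_gene_name(raw: str) -> str:
    """Map an annotation string to one of the 37 canonical tokens.

    Raises ``ValueError`` for anything it cannot place, including leucine or
    serine tRNAs whose anticodon family (L1/CUN vs L2/UUR; S1/AGN vs S2/UCN)
    is not recoverable from the string.
    """
    name = raw.strip()
    if name in CANONICAL_SET:
        return name
    low = name.lower()
    if low in SYNONYMS:
        return SYNONYMS[low]

    # tRNA spellings: trnX, trnX-xxx, tRNA-Xyz, tRNA-Leu(UUR), trnL(CUN)...
    if low.startswith(("trn", "trna", "trna-", "trna_")):
        body = low
        for prefix in ("trna-", "trna_", "trna", "trn"):
            if body.startswith(prefix):
                body = body[len(prefix):]
                break
        body = body.strip("-_ ")
        codon = None
        if "(" in body and body.endswith(")"):
            body, codon = body[:-1].split("(", 1)
            codon = codon.strip().upper().replace("T", "U")
            body = body.strip("-_ ")
        key = body.lower()
        if key in ("l", "leu", "leucine", "l1", "l2"):
            if key == "l1" or codon == "CUN":
                return "trnL1"
            if key == "l2" or codon == "UUR":
                return "trnL2"
            raise ValueError(
                f"ambiguous leucine tRNA {raw!r}: anticodon family "
                "(CUN vs UUR) not specified"
            )
        if key in ("s", "ser", "serine", "s1", "s2"):
            if key == "s1" or codon == "AGN":
                return "trnS1"
            if key == "s2" or codon == "UCN":
                return "trnS2"
            raise ValueError(
                f"ambiguous serine tRNA {raw!r}: anticodon family "
                "(AGN vs UCN) not specified"
            )
        if len(key) == 1 and key.upper() in _AA_SINGLE:
            return _AA_SINGLE[key.upper()]
        if key in _AA3:
            return _AA3[key]

    raise ValueError(f"unrecognizable gene name: {raw!r}")
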
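"""Built-in p53-SBP fusion construct used by examples and tests.

The fusion is assembled from the canonical human p53 protein sequence
(UniProt P04637, 393 residues), a 4-residue synthetic linker, and the
38-residue streptavidin-binding peptide (SBP) tag, giving a 435-residue
protein whose natural termination codon sits at codon 436. The linker
residues (GSGS) are a synthetic choice: only the spacing between p53 and the
tag is constrained by the fusion coordinate system, not the residues
themselves.

The CDS is a synthetic back-translation (one fixed codon per residue; codon
213 forced to CGA, the codon whose nonsense mutation produces the recurrent
R213X allele). The 3' sequence downstream of the terminal stop is likewise
synthetic; its first six codons (ending in TGT, cysteine) were chosen so the
C-terminal stop-skip product is consistent with the printed precursor mass of
the observed skip peptide. None of these synthetic regions is used as ground
truth by the package; they make every event class exercisable end-to-end.
"""

from __future__ import annotations

from .errors import InputError
from .proteoforms import CodingConstruct, StopCodonSite, apply_codon_edits

# Canonical human p53 (P04637), 393 residues.
P53_PROTEIN = (
    "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGP"
    "DEAPRMPEAAPPVAPAPAAPTPAAPAPAPSWPLSSSVPSQKTYQGSYGFRLGFLHSGTAK"
    "SVTCTYSPALNKMFCQLAKTCPVQLWVDSTPPPGTRVRAMAIYKQSQHMTEVVRRCPHHE"
    "RCSDSDGLAPPQHLIRVEGNLRVEYLDDRNTFRHSVVVPYEPPEVGSDCTTIHYNYMCNS"
    "SCMGGMNRRPILTIITLEDSSGNLLGRNSFEVRVCACPGRDRRTEEENLRKKGEPHHELP"
    "PGSTKRALPNNTSSSPQPKKKPLDGEYFTLQIRGRERFEMFRELNEALELKDAQAGKEPG"
    "GSRAHSSHLKSKKGQSTSRHKKLMFKTEGPDSD"
)

#: Streptavidin-binding peptide tag, 38 residues.
SBP_TAG = "MDEKTTGWRGGHVVEGLAGELEQLRARLEHHPQGQREP"

#: Synthetic 4-residue linker between p53 and the SBP tag.
LINKER = "GSGS"

FUSION_PROTEIN = P53_PROTEIN + LINKER + SBP_TAG  # 435 residues

#: Codon number of the fusion's natural termination codon.
TERMINAL_STOP_CODON = len(FUSION_PROTEIN) + 1  # 436

_BACK_TRANSLATION_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

# Synthetic 3' sequence after the terminal stop: six codons (TAAAAC, ending
# with a TGT cysteine codon) before the next in-frame stop, then a tail with
# stop codons in all three frames so frameshift products terminate.
DOWNSTREAM_NT = "ACCGCCGCCGCCGCCTGT" + "TAA" + "TAGA" * 6


def back_translate(protein: str, codon_overrides: dict[int, str] | None = None) -> str:
    """Fixed-codon back-translation; ``codon_overrides`` maps 1-based codon
    numbers to explicit triplets."""
    overrides = codon_overrides or {}
    try:
        codons = [
            overrides.get(i, _BACK_TRANSLATION_CODON[aa])
            for i, aa in enumerate(protein, start=1)
        ]
    except KeyError as exc:
        raise InputError(f"cannot back-translate residue {exc.args[0]!r}") from None
    return "".join(codons)


def p53_sbp_construct(ptc: str | None = None) -> CodingConstruct:
    """The p53-SBP fusion construct, optionally with one premature stop.

    ``ptc`` is a site label such as ``"TGA129"``, ``"TAA129"``, ``"TAG129"``,
    ``"TGA127"``, ``"TGA128"`` or ``"TGA213"``: the stop triplet followed by
    the 1-based codon number. The natural terminal stop is always declared as
    site ``"STOP436"``.
    """
    cds = (
        back_translate(FUSION_PROTEIN, codon_overrides={213: "CGA"})
        + "TAA"
        + DOWNSTREAM_NT
    )
    terminal = StopCodonSite(TERMINAL_STOP_CODON, "TAA", f"STOP{TERMINAL_STOP_CODON}")
    construct = CodingConstruct(name="P53SBP", cds=cds, sites=(terminal,))
    if ptc is None:
        return construct
    triplet, index_txt = ptc[:3], ptc[3:]
    if triplet not in ("TAA", "TAG", "TGA") or not index_txt.isdigit():
        raise InputError(f"PTC label {ptc!r} must look like 'TGA129'")
    index = int(index_txt)
    if not 1 <= index <= len(FUSION_PROTEIN):
        raise InputError(f"PTC codon {index} outside the fusion protein")
    edited = apply_codon_edits(construct, [(index, triplet)])
    return CodingConstruct(
        name="P53SBP",
        cds=edited.cds,
        sites=(StopCodonSite(index, triplet, ptc), terminal),
        metadata={"ptc": ptc},
    )


def kppk_edits() -> list[tuple[int, str]]:
    """Codon edits replacing 221-EPPE-224 with 221-KPPK-224 (E->K at 221 and
    224), introducing tryptic cleavage sites next to codon 213."""
    return [(221, "AAG"), (224, "AAG")]
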
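"""Curated SRM peptide panel for meningioma marker proteins.

Fifteen proteotypic tryptic peptides (three per protein) covering five
proteins with established roles in meningioma pathobiology: vimentin
(VIM), annexin A2 (ANXA2), cytoskeleton-associated protein 4 (CKAP4),
chloride intracellular channel 1 (CLIC1) and eukaryotic translation
initiation factor 4 gamma 1 (EIF4G1).  All peptides end in K or R, carry
no internal tryptic site and are released intact by complete tryptic
digestion, which makes them directly monitorable on a triple quadrupole.
"""

MENINGIOMA_SRM_PANEL: dict[str, tuple[str, ...]] = {
    "VIM": ("DNLAEDIMR", "LQEEMLQR", "QDVDNASLAR"),
    "ANXA2": ("AYTNFDAER", "QIAFAYQR", "TPAQYDASELK"),
    "CKAP4": ("LPPQDFLDR", "ASVSQVEADLK", "TAVDSLVAYSVK"),
    "CLIC1": ("IGNCPFSQR", "LAALNPESNTAGLDIFAK", "GFTIPEAFR"),
    "EIF4G1": ("QVTVLAIDTEER", "GVIDLIFEK", "VEYTLGEESEAPGQR"),
}

#: All 15 panel peptides in a stable order (by protein, then panel order).
PANEL_PEPTIDES: tuple[str, ...] = tuple(
    pep for protein in MENINGIOMA_SRM_PANEL for pep in MENINGIOMA_SRM_PANEL[protein]
)
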
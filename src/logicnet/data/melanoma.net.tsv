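# TRAIL-receptor agonist signaling network for melanoma contextualization.
# Synthetic reconstruction: the three named inhibitory edges
# (FLIP -| cleaved caspase-8, BCL2 -| cleaved caspase-3, XIAP -| cleaved
# caspase-3) and the canonical TRAIL->caspase, TRAIL->NFkB->(FLIP, XIAP),
# BRAF(V600E)->MEK->ERK and PI3K->AKT chains are literature-anchored; the
# remaining edges complete the topology to 19 nodes / 29 parameters.
node IZI input
node TRAILR latent
node Casp8 latent
node FLIP measured
node Casp3 latent
node BCL2 latent
node XIAP measured
node PARP measured
node Apoptosis readout
node SMAC latent
node TAK1 latent
node IKK latent
node AKT measured
node IkBa measured
node NFkB measured
node BRAF latent constitutive
node MEK latent
node ERK measured
node PI3K latent
IZI -> TRAILR k_izi_trailr
TRAILR -> Casp8 k_trailr_casp8
FLIP -| Casp8 k_flip_casp8
Casp8 -> Casp3 k_casp8_casp3
BCL2 -| Casp3 k_bcl2_casp3
XIAP -| Casp3 k_xiap_casp3
Casp3 -> PARP k_casp3_parp
PARP -> Apoptosis k_parp_apopt
Casp3 -> Casp8 k_casp3_casp8
Casp8 -> SMAC k_casp8_smac
SMAC -| XIAP k_smac_xiap
TRAILR -> TAK1 k_trailr_tak1
TAK1 -> IKK k_tak1_ikk
AKT -> IKK k_akt_ikk
IKK -| IkBa k_ikk_ikba
NFkB -> IkBa k_nfkb_ikba
IkBa -| NFkB k_ikba_nfkb
IKK -> NFkB k_ikk_nfkb
NFkB -> FLIP k_nfkb_flip
NFkB -> XIAP k_nfkb_xiap
NFkB -> BCL2 k_nfkb_bcl2
BRAF -> MEK k_braf_mek
MEK -> ERK k_mek_erk
ERK -> FLIP k_erk_flip
TRAILR -> PI3K k_trailr_pi3k
PI3K -> AKT k_pi3k_akt
AKT -| Casp3 k_akt_casp3
AKT -> XIAP k_akt_xiap
Casp3 -> Apoptosis k_casp3_apopt
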
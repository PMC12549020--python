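# Default matrisome domain rule set.
#
# Categories follow the Hynes/Naba matrisome framework: a core matrisome
# (collagens, proteoglycans, ECM glycoproteins), matrisome-associated factors
# (ECM regulators, ECM-affiliated proteins, secreted factors), transmembrane
# adhesion receptors (adhesome), and an other-ECM catch-all.  Category order
# is precedence order: the first category whose inclusion domains match, whose
# signal/membrane requirements hold, and whose exclusion domains do NOT match
# wins.  Accessions are InterPro plus a few Pfam/SMART equivalents so that a
# rule set can be matched against either accession space.
#
# The lists below are a working default assembled from the published category
# signatures (EGF, LamG, TSP1, vWFA, collagen triple helix, ...); they are
# deliberately editable — real studies curate their own lists.

categories:
  - name: collagens
    division: core
    inclusion: [IPR008160, PF01391, IPR000885, PF01410, IPR001007]
    exclusion: [IPR000719, PF00069]
    requires_signal: true
    membrane: forbidden
  - name: proteoglycans
    division: core
    inclusion: [IPR001611, PF13855, IPR000884]
    exclusion: [IPR000719, PF00069, IPR002126, IPR008160]
    requires_signal: true
    membrane: forbidden
  - name: ecm_glycoproteins
    division: core
    inclusion: [IPR002035, PF00092, IPR001791, PF02210, IPR000884, PF00090,
                IPR000742, PF00008, IPR003961, PF00041, IPR002181]
    exclusion: [IPR000719, PF00069, IPR002126, PF00028]
    requires_signal: true
    membrane: forbidden
  - name: ecm_regulators
    division: associated
    inclusion: [IPR001506, PF01400, IPR001818, PF00413, IPR001820, PF00965,
                IPR000215, PF00079, IPR002223, PF00014]
    exclusion: [IPR000719, PF00069]
    requires_signal: true
    membrane: any
  - name: ecm_affiliated
    division: associated
    inclusion: [IPR001304, PF00059, IPR001079, PF00337, IPR001627, PF01403]
    exclusion: [IPR000719, PF00069]
    requires_signal: false
    membrane: any
  - name: secreted_factors
    division: associated
    inclusion: [IPR005817, PF00110, IPR001839, PF00019, IPR000867, PF00219,
                IPR002350, PF00050]
    exclusion: [IPR000719, PF00069]
    requires_signal: true
    membrane: forbidden
  - name: adhesion_receptors
    division: adhesome
    inclusion: [IPR002126, PF00028, IPR013517, PF01839, IPR000413, PF00357,
                IPR007110, PF00047]
    exclusion: []
    requires_signal: false
    membrane: required
  - name: other_ecm
    division: other
    inclusion: [IPR008197, PF00095, IPR000010, PF00031, IPR002007]
    exclusion: [IPR000719, PF00069]
    requires_signal: false
    membrane: any

# Bona fide ECM domains: the high-confidence signature subset used at the
# curation step.  Candidates whose only matching accessions fall outside this
# list (e.g. ECM-affiliated lectins) are dropped from the curated set.
bona_fide:
  [IPR008160, PF01391, IPR000885, PF01410, IPR001007,
   IPR001611, PF13855,
   IPR002035, PF00092, IPR001791, PF02210, IPR000884, PF00090,
   IPR000742, PF00008, IPR003961, PF00041, IPR002181,
   IPR001506, PF01400, IPR001818, PF00413, IPR001820, PF00965,
   IPR000215, PF00079, IPR002223, PF00014,
   IPR005817, PF00110, IPR001839, PF00019, IPR000867, PF00219,
   IPR002350, PF00050,
   IPR002126, PF00028, IPR013517, PF01839, IPR000413, PF00357,
   IPR008197, PF00095, IPR000010, PF00031, IPR002007]
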
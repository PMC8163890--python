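# Therapeutic-function catalog used to profile strain annotation tables.
# A function is present when >= min_groups_required marker groups each match
# (default: all groups); matching is case-insensitive substring on product
# text or exact term-id match.
functions:
  - function_id: butyrate
    display_name: butyrate synthesis
    marker_groups:
      - [butyrate kinase, "butyryl-CoA:acetate CoA-transferase"]
  - function_id: propionate
    display_name: propionate synthesis
    marker_groups:
      - [methylmalonyl-CoA decarboxylase, propionate CoA-transferase]
  - function_id: gaba
    display_name: gamma-aminobutyrate synthesis
    marker_groups:
      - [glutamate decarboxylase]
  - function_id: indole
    display_name: indole synthesis from tryptophan
    marker_groups:
      - [tryptophanase]
  - function_id: siderophore_synthesis
    display_name: siderophore synthesis
    marker_groups:
      - [siderophore synthesis, yersiniabactin synthesis, enterobactin synthesis]
  - function_id: siderophore_uptake
    display_name: heterologous siderophore uptake
    marker_groups:
      - [siderophore uptake, ferrichrome uptake, enterobactin uptake, aerobactin uptake]
  - function_id: siderophore
    display_name: siderophore activity (synthesis or uptake)
    marker_groups:
      - [siderophore synthesis, yersiniabactin synthesis, enterobactin synthesis,
         siderophore uptake, ferrichrome uptake, enterobactin uptake, aerobactin uptake]
  - function_id: cgh
    display_name: choloylglycine hydrolase (bile-salt deconjugation)
    marker_groups:
      - [choloylglycine hydrolase, bile salt hydrolase]
  - function_id: hsd_3a
    display_name: 3-alpha-hydroxysteroid dehydrogenase
    marker_groups:
      - [3-alpha-hydroxysteroid dehydrogenase]
  - function_id: hsd_3b
    display_name: 3-beta-hydroxysteroid dehydrogenase
    marker_groups:
      - [3-beta-hydroxysteroid dehydrogenase]
  - function_id: hsd_7a
    display_name: 7-alpha-hydroxysteroid dehydrogenase
    marker_groups:
      - [7-alpha-hydroxysteroid dehydrogenase]
  - function_id: hsd_7b
    display_name: 7-beta-hydroxysteroid dehydrogenase
    marker_groups:
      - [7-beta-hydroxysteroid dehydrogenase]
  - function_id: dh_7a
    display_name: 7-alpha-dehydratase
    marker_groups:
      - [7-alpha-dehydratase]
  - function_id: dh_7b
    display_name: 7-beta-dehydratase
    marker_groups:
      - [7-beta-dehydratase]
  - function_id: dh_7ab
    display_name: 7-alpha/beta-dehydratase (secondary bile-acid synthesis)
    marker_groups:
      - [7-alpha-dehydratase, 7-beta-dehydratase]
  - function_id: dh_3a
    display_name: 3-alpha-hydroxy bile acid-CoA-ester-3 dehydrogenase
    marker_groups:
      - [3-alpha-hydroxy bile acid-CoA-ester-3 dehydrogenase]
  - function_id: oxo_3_5a
    display_name: 3-oxo-5-alpha-steroid-4-dehydrogenase
    marker_groups:
      - [3-oxo-5-alpha-steroid-4-dehydrogenase]
  - function_id: lcd
    display_name: L-carnitine hydratase
    marker_groups:
      - [L-carnitine hydratase]
  - function_id: sbs
    display_name: sodium-bile acid symporter
    marker_groups:
      - [sodium-bile acid symporter]
  - function_id: taurine_uptake
    display_name: taurine uptake
    marker_groups:
      - [taurine uptake]
  - function_id: bile_salt
    display_name: bile-salt deconjugation / bile-acid conversion (any enzyme)
    marker_groups:
      - [choloylglycine hydrolase, bile salt hydrolase,
         3-alpha-hydroxysteroid dehydrogenase, 3-beta-hydroxysteroid dehydrogenase,
         7-alpha-hydroxysteroid dehydrogenase, 7-beta-hydroxysteroid dehydrogenase,
         7-alpha-dehydratase, 7-beta-dehydratase,
         3-alpha-hydroxy bile acid-CoA-ester-3 dehydrogenase,
         3-oxo-5-alpha-steroid-4-dehydrogenase,
         L-carnitine hydratase, sodium-bile acid symporter, taurine uptake]
  - function_id: bacteriocin
    display_name: bacteriocin synthesis
    marker_groups:
      - [bacteriocin, lantibiotic, lantipeptide, lactococcin, linocin]
  - function_id: antimicrobial
    display_name: antimicrobial synthesis (bacteriocin or lantibiotic)
    marker_groups:
      - [bacteriocin, lantibiotic, lantipeptide, lactococcin, linocin]
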
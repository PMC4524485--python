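# Default haplogroup-E marker hierarchy.
#
# Encodes the published topology of the genotyped marker tree as far as it
# is stated in text: the basal E dichotomy (V3725 | M75) with P147 sister
# to the new deep branch E-V44; the M215 -> M35 | V16 split; the M35
# bifurcation into Z827 and V68; the tripartite E-V1515 clade (V1486,
# V1700); and the revised M78 substructure.  Each node lists its
# phylogenetically equivalent defining mutations.  "stage" orders sibling
# screening: V16 is only typed on the M215*(xM35) remainder.
label: E
mutations: [M40, M96]
children:
  - label: E-V3725
    mutations: [V3725]
    children:
      - label: E-P147
        mutations: [P147, V1844, V1865]
        children:
          - label: E-M33
            mutations: [M33]
          - label: E-P2
            mutations: [P2]
            children:
              - label: E-V38
                mutations: [V38]
                children:
                  - label: E-M2
                    mutations: [M2]
                    children:
                      - label: E-U209
                        mutations: [U209]
                        children:
                          - label: E-V2580
                            mutations: [V2580]
                  - label: E-M329
                    mutations: [M329]
              - label: E-M215
                mutations: [M215]
                children:
                  - label: E-M35
                    mutations: [M35]
                    stage: 0
                    children:
                      - label: E-Z827
                        mutations: [Z827]
                        children:
                          - label: E-V257
                            mutations: [V257]
                            children:
                              - label: E-M81
                                mutations: [M81]
                          - label: E-M123
                            mutations: [M123]
                          - label: E-V1515
                            mutations: [V1515]
                            children:
                              - label: E-V1486
                                mutations: [V1486]
                                children:
                                  - label: E-M293
                                    mutations: [M293]
                                  - label: E-V92
                                    mutations: [V92]
                                  - label: E-V2881
                                    mutations: [V2881]
                              - label: E-V1700
                                mutations: [V1700]
                                children:
                                  - label: E-V42
                                    mutations: [V42]
                                  - label: E-V1785
                                    mutations: [V1785]
                                    children:
                                      - label: E-V6
                                        mutations: [V6]
                                      - label: E-V1472
                                        mutations: [V1472, V1617, V2793,
                                                    V2684, V2727, V2802,
                                                    V2927]
                      - label: E-V68
                        mutations: [V68]
                        children:
                          - label: E-M78
                            mutations: [M78]
                            children:
                              - label: E-V1477
                                mutations: [V1477]
                              - label: E-V1083
                                mutations: [V1083]
                                children:
                                  - label: E-V13
                                    mutations: [V13]
                                  - label: E-V22
                                    mutations: [V22]
                              - label: E-V12
                                mutations: [V12]
                              - label: E-V264
                                mutations: [V264]
                                children:
                                  - label: E-V65
                                    mutations: [V65]
                                  - label: E-V259
                                    mutations: [V259]
                          - label: E-V2009
                            mutations: [V2009, V2955]
                  - label: E-V16
                    mutations: [V16]
                    stage: 1
      - label: E-V44
        mutations: [V44]
  - label: E-M75
    mutations: [M75]
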
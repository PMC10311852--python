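{
 "semantic_types": [
  "aapp",
  "acab",
  "acty",
  "aggp",
  "amas",
  "amph",
  "anab",
  "anim",
  "anst",
  "antb",
  "arch",
  "bacs",
  "bact",
  "bdsu",
  "bdsy",
  "bhvr",
  "biof",
  "bird",
  "blor",
  "bmod",
  "bodm",
  "bpoc",
  "bsoj",
  "celc",
  "celf",
  "cell",
  "cgab",
  "chem",
  "chvf",
  "chvs",
  "clas",
  "clna",
  "clnd",
  "cnce",
  "comd",
  "crbs",
  "diap",
  "dora",
  "drdd",
  "dsyn",
  "edac",
  "eehu",
  "elii",
  "emod",
  "emst",
  "enty",
  "enzy",
  "euka",
  "evnt",
  "famg",
  "ffas",
  "fish",
  "fndg",
  "fngs",
  "food",
  "ftcn",
  "genf",
  "geoa",
  "gngm",
  "gora",
  "grpa",
  "grup",
  "hcpp",
  "hcro",
  "hlca",
  "hops",
  "horm",
  "humn",
  "idcn",
  "imft",
  "inbe",
  "inch",
  "inpo",
  "inpr",
  "irda",
  "lang",
  "lbpr",
  "lbtr",
  "mamm",
  "mbrt",
  "mcha",
  "medd",
  "menp",
  "mnob",
  "mobd",
  "moft",
  "mosq",
  "neop",
  "nnon",
  "npop",
  "nusq",
  "ocac",
  "ocdi",
  "orch",
  "orga",
  "orgf",
  "orgm",
  "orgt",
  "ortf",
  "patf",
  "phob",
  "phpr",
  "phsf",
  "phsu",
  "plnt",
  "podg",
  "popg",
  "prog",
  "pros",
  "qlco",
  "qnco",
  "rcpt",
  "rept",
  "resa",
  "resd",
  "rnlw",
  "sbst",
  "shro",
  "socb",
  "sosy",
  "spco",
  "tisu",
  "tmco",
  "topp",
  "virs",
  "vita",
  "vtbt"
 ],
 "relations": [
  "ADMINISTERED_TO",
  "AFFECTS",
  "ASSOCIATED_WITH",
  "AUGMENTS",
  "CAUSES",
  "COEXISTS_WITH",
  "COMPLICATES",
  "CONVERTS_TO",
  "DIAGNOSES",
  "DISRUPTS",
  "INHIBITS",
  "INTERACTS_WITH",
  "LITERATURE_DTI",
  "LOCATION_OF",
  "MANIFESTATION_OF",
  "METHOD_OF",
  "OCCURS_IN",
  "PART_OF",
  "PRECEDES",
  "PREDISPOSES",
  "PREVENTS",
  "PROCESS_OF",
  "PRODUCES",
  "STIMULATES",
  "TREATS",
  "USES",
  "MEASURES",
  "MEASUREMENT_OF",
  "SAME_AS",
  "COMPARED_WITH",
  "HIGHER_THAN",
  "LOWER_THAN",
  "EXHIBITS",
  "MENTIONED_IN",
  "HAS_MESH"
 ],
 "auxiliary_relations": [
  "is_a"
 ]
}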
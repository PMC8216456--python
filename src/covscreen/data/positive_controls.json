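{
  "description": "Composition of the 80-RNA positive-control set used to tune the candidate criteria: all annotated single-copy structural RNA genes of S. cerevisiae excluding C/D box snoRNAs (too little covariation power) and the SSU/LSU rRNAs (unrepresentative length and copy number).",
  "categories": {
    "haca_snorna": {
      "count": 29,
      "members": [
        "snR3", "snR5", "snR8", "snR9", "snR10", "snR11", "snR30", "snR31",
        "snR32", "snR33", "snR34", "snR35", "snR36", "snR37", "snR42",
        "snR43", "snR44", "snR46", "snR49", "snR80", "snR81", "snR82",
        "snR83", "snR84", "snR85", "snR86", "snR161", "snR189", "snR191"
      ]
    },
    "rRNA": {
      "count": 2,
      "members": ["5S_rRNA", "5.8S_rRNA"]
    },
    "tRNA": {
      "count": 39,
      "members": [
        "tRNA-Ala-AGC", "tRNA-Arg-ACG", "tRNA-Arg-CCG", "tRNA-Arg-CCU",
        "tRNA-Arg-UCU", "tRNA-Asn-GUU", "tRNA-Asp-GUC", "tRNA-Cys-GCA",
        "tRNA-Gln-CUG", "tRNA-Gln-UUG", "tRNA-Glu-CUC", "tRNA-Glu-UUC",
        "tRNA-Gly-CCC", "tRNA-Gly-GCC", "tRNA-Gly-UCC", "tRNA-His-GUG",
        "tRNA-Ile-AAU", "tRNA-Ile-UAU", "tRNA-Leu-CAA", "tRNA-Leu-GAG",
        "tRNA-Leu-UAA", "tRNA-Leu-UAG", "tRNA-Lys-CUU", "tRNA-Lys-UUU",
        "tRNA-Met-CAU", "tRNA-Phe-GAA", "tRNA-Pro-AGG", "tRNA-Pro-UGG",
        "tRNA-Ser-AGA", "tRNA-Ser-CGA", "tRNA-Ser-GCU", "tRNA-Ser-UGA",
        "tRNA-Thr-AGU", "tRNA-Thr-CGU", "tRNA-Thr-UGU", "tRNA-Trp-CCA",
        "tRNA-Tyr-GUA", "tRNA-Val-AAC", "tRNA-Val-UAC"
      ]
    },
    "spliceosomal": {
      "count": 5,
      "members": ["U1", "U2", "U4", "U5", "U6"]
    },
    "singleton": {
      "count": 5,
      "members": ["U3", "Telomerase_RNA", "RNase_MRP", "RNase_P", "SRP_RNA"]
    }
  }
}
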
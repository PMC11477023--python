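{
  "neuronal": {
    "subcellular_thpa": [],
    "subcellular_uniprot": [
      "axon",
      "dendrite",
      "midbody",
      "synaptic vesicle membrane",
      "neuronal cell body",
      "axon initial segment",
      "terminal bouton",
      "dendritic spine",
      "postsynaptic density of dendrite",
      "neuron projection",
      "presynaptic membrane",
      "synapse",
      "postsynaptic membrane",
      "cell body",
      "synaptic cleft",
      "myelin sheath",
      "synaptic vesicle",
      "paranode region of axon",
      "dendritic branch",
      "excitatory synapse"
    ],
    "tissue_thpa": [
      "caudate",
      "cerebellum",
      "cerebral cortex",
      "hippocampus"
    ],
    "tissue_uniprot": [
      "cerebrospinal fluid",
      "peripheral nerve",
      "pituitary",
      "substantia nigra",
      "temporal cortex",
      "glial cell",
      "brain stem",
      "hippocampus",
      "cerebellum",
      "nervous system",
      "neuron",
      "astrocyte",
      "schwann cell",
      "nerve",
      "brain"
    ]
  },
  "vascular": {
    "subcellular_thpa": [],
    "subcellular_uniprot": [],
    "tissue_thpa": [
      "smooth muscle"
    ],
    "tissue_uniprot": [
      "vascular smooth muscle",
      "smooth muscle cell",
      "smooth muscle",
      "endothelial cell"
    ]
  }
}
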
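{
  "version": "0.1.0",
  "categories": [
    "projectScope",
    "libraryGeneration",
    "libraryIntegrationExpression",
    "assayType",
    "sequencingMethod",
    "phenotypeRelevance"
  ],
  "terms": [
    {"category": "projectScope", "label": "protein coding element", "definition": "Target is a protein-coding sequence assayed at nucleotide or amino-acid resolution."},
    {"category": "projectScope", "label": "noncoding regulatory element", "definition": "Target is a promoter, enhancer, or other regulatory sequence."},
    {"category": "projectScope", "label": "splicing element", "definition": "Target is a splice site or other splicing-relevant sequence."},
    {"category": "projectScope", "label": "multiple or other element", "definition": "Scope spanning several element classes or not covered above."},
    {"category": "libraryGeneration", "label": "endogenous locus library method", "definition": "Variant library created by editing at the endogenous locus."},
    {"category": "libraryGeneration", "label": "in vitro library method", "definition": "Variant library constructed in vitro and delivered to the system."},
    {"category": "libraryGeneration", "label": "saturation genome editing", "definition": "CRISPR-mediated saturation editing at the endogenous locus."},
    {"category": "libraryGeneration", "label": "base editor scan", "definition": "Tiled base-editing screen at the endogenous locus."},
    {"category": "libraryGeneration", "label": "prime editing scan", "definition": "Tiled prime-editing screen at the endogenous locus."},
    {"category": "libraryGeneration", "label": "doped oligonucleotide synthesis", "definition": "In vitro library from doped synthetic oligonucleotides."},
    {"category": "libraryGeneration", "label": "site-directed mutagenesis", "definition": "In vitro programmed mutagenesis (e.g., inverse PCR, nicking mutagenesis)."},
    {"category": "libraryGeneration", "label": "error-prone PCR", "definition": "In vitro random mutagenesis by low-fidelity amplification."},
    {"category": "libraryGeneration", "label": "microarray-synthesized oligo pool", "definition": "In vitro library from array-synthesized oligo pools."},
    {"category": "libraryIntegrationExpression", "label": "lentiviral transduction", "definition": "Library delivered by lentiviral integration."},
    {"category": "libraryIntegrationExpression", "label": "adeno-associated virus transduction", "definition": "Library delivered by AAV."},
    {"category": "libraryIntegrationExpression", "label": "plasmid transfection", "definition": "Episomal expression from transfected plasmid."},
    {"category": "libraryIntegrationExpression", "label": "landing pad recombination", "definition": "Single-copy integration at an engineered landing pad."},
    {"category": "libraryIntegrationExpression", "label": "electroporation", "definition": "Library delivered by electroporation."},
    {"category": "libraryIntegrationExpression", "label": "chemical transformation", "definition": "Library delivered by chemical transformation (microbial systems)."},
    {"category": "libraryIntegrationExpression", "label": "endogenous expression after editing", "definition": "Variants expressed from the edited endogenous locus."},
    {"category": "assayType", "label": "flow cytometry assay", "curie": "OBI:0000916", "definition": "Readout by fluorescence-activated sorting or analysis."},
    {"category": "assayType", "label": "cell survival or growth assay", "definition": "Readout by depletion or enrichment under selection."},
    {"category": "assayType", "label": "fluorescence reporter assay", "definition": "Readout by a fluorescent reporter of target function."},
    {"category": "assayType", "label": "protein binding assay", "definition": "Readout by binding to a partner (e.g., display selection)."},
    {"category": "assayType", "label": "transcriptional reporter assay", "definition": "Readout by transcriptional output of a reporter construct."},
    {"category": "assayType", "label": "enzymatic activity assay", "definition": "Readout by catalytic activity of the target."},
    {"category": "sequencingMethod", "label": "targeted amplicon sequencing", "definition": "Direct sequencing of the mutagenized region."},
    {"category": "sequencingMethod", "label": "barcode counting sequencing", "definition": "Counting of variant-linked barcodes."},
    {"category": "sequencingMethod", "label": "shotgun sequencing", "definition": "Fragmented whole-construct sequencing."},
    {"category": "sequencingMethod", "label": "long-read sequencing", "definition": "Full-length single-molecule reads over the target."},
    {"category": "sequencingMethod", "label": "paired-end subassembly", "definition": "Linked short reads assembled into full-length genotypes."},
    {"category": "phenotypeRelevance", "label": "Mendelian disease relevance", "definition": "Assay probes a mechanism underlying a Mendelian condition."},
    {"category": "phenotypeRelevance", "label": "cancer relevance", "definition": "Assay probes somatic or germline cancer variant function."},
    {"category": "phenotypeRelevance", "label": "pharmacogenomic relevance", "definition": "Assay probes drug response or metabolism."},
    {"category": "phenotypeRelevance", "label": "molecular function only", "definition": "Assay probes molecular function without a named disease link."}
  ]
}
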
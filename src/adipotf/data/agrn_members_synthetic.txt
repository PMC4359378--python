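# Synthetic reconstruction of an adipogenic gene-regulatory-network
# membership list, assembled from transcription factors and targets
# repeatedly named in the adipogenesis literature (WikiPathways
# "Adipogenesis" scaffold and reviews). It stands in for a study-
# specific curation and is intended for demonstrations and tests.
Pparg
Cebpa
Cebpb
Cebpd
Srebf1
Klf4
Klf5
Klf15
Zeb1
Stat5a
Stat5b
Creb1
Ddit3
Gata2
Gata3
Egr2
Zbtb16
Sirt1
Ncor1
Ncor2
Rxra
Nr3c1
Foxo1
Tcf7l2
Wnt10b
Dlk1
Adipoq
Lep
Lpl
Fabp4
Plin1
Agt
Angpt2
Bmp2
Bmp4
Igf1
Irs1
Irs2
Lmna
Mef2c
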
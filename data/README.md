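# data/

Place the published per-gene supplementary decay table here as
`table_s1.csv` to enable the genome-wide refit (acceptance targets t1–t5
and the corresponding acceptance test). The file is third-party data and is
therefore not shipped with the repository.

Expected layout: a CSV whose first column is the gene id and whose
measured-level columns are named by their time points in minutes
(`0,5,10,15,20,30,40,50,60`); extra metadata columns (category, rates, RSS,
...) are ignored by the reader.
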
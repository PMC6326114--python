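#!/usr/bin/env Rscript
# Export the anonymized RA1/RA2 benchmark (binarized diagnosis-code
# matrices for the 6- and 11-year spans, plus the silver-standard pairs)
# from the CRAN package `ludic` into the CSV/TSV dialect this package
# reads.  Requires: install.packages("ludic").
#
# Usage: Rscript scripts/export_ludic_benchmark.R [outdir=data/benchmark]
#
# Object names inside the ludic package should be confirmed against the
# installed version (`data(package = "ludic")`); adjust below if needed.

args <- commandArgs(trailingOnly = TRUE)
outdir <- if (length(args) >= 1) args[1] else "data/benchmark"
dir.create(outdir, recursive = TRUE, showWarnings = FALSE)

library(ludic)
datasets <- data(package = "ludic")$results[, "Item"]
message("datasets in ludic: ", paste(datasets, collapse = ", "))

write_bin <- function(mat, path) {
  df <- data.frame(patient_id = rownames(mat), as.data.frame(mat),
                   check.names = FALSE)
  write.csv(df, path, row.names = FALSE, quote = FALSE)
}

for (nm in datasets) {
  data(list = nm, package = "ludic")
  obj <- get(nm)
  if (is.matrix(obj) || is.data.frame(obj)) {
    if (grepl("silver|match|pair", nm, ignore.case = TRUE)) {
      write.table(obj, file.path(outdir, "silver_standard.tsv"),
                  sep = "\t", row.names = FALSE, quote = FALSE)
    } else {
      write_bin(as.matrix(obj), file.path(outdir, paste0(nm, ".csv")))
    }
  }
}
message("exported to ", outdir,
        "; rename files to RA1_6y.csv / RA2_6y.csv / RA1_11y.csv / ",
        "RA2_11y.csv / silver_standard.tsv as appropriate")
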
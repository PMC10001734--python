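{
  "SH1":  {"kind": "ratio-percent", "metric": "% of ED wards with suitable infrastructure", "numerator": "wards with suitable infrastructure", "denominator": "total wards", "units": "%"},
  "SH2":  {"kind": "ratio-percent", "metric": "% of ED wards without suitable illumination and cleansing", "numerator": "wards without suitable illumination/cleansing", "denominator": "total wards", "units": "%"},
  "SH3":  {"kind": "binary", "metric": "availability of sanitary installations", "condition": "ready to use", "units": ""},
  "SH4":  {"kind": "binary", "metric": "delineation of ED areas", "condition": "delineated", "units": ""},
  "SH5":  {"kind": "count", "metric": "beds available for respiratory-outbreak patients", "units": "beds"},
  "SH6":  {"kind": "ratio-percent", "metric": "% of ready-to-use healthcare equipment", "numerator": "ready-to-use devices", "denominator": "total devices", "units": "%"},
  "SH7":  {"kind": "ratio-percent", "metric": "% of medical equipment pertinent to outbreak requirements", "numerator": "pertinent devices", "denominator": "total devices", "units": "%"},
  "SH8":  {"kind": "ratio-percent", "metric": "% of flawed medical equipment", "numerator": "flawed devices", "denominator": "total devices", "units": "%"},
  "SH9":  {"kind": "binary", "metric": "design of outbreak medical care procedures", "condition": "designed", "units": ""},
  "SH10": {"kind": "ratio-percent", "metric": "% of widespread procedures and protocols", "numerator": "disseminated protocols", "denominator": "total protocols", "units": "%"},
  "SH11": {"kind": "ratio-percent", "metric": "% of monitored adverse events", "numerator": "supervised adverse events", "denominator": "total adverse events", "units": "%"},
  "SH12": {"kind": "mean-interval", "metric": "average turnaround time for radiology outcomes", "numerator": "sum of delivery-order gaps", "denominator": "number of radiology tests", "units": "min"},
  "SH13": {"kind": "mean-interval", "metric": "average turnaround time for lab results", "numerator": "sum of delivery-order gaps", "denominator": "number of lab tests", "units": "min"},
  "SH14": {"kind": "mean-interval", "metric": "average transfer time to hospitalization bed", "numerator": "sum of transfer delays", "denominator": "number of transfers", "units": "h"},
  "SH15": {"kind": "mean-interval", "metric": "average lead time for medication delivery", "numerator": "sum of delivery lead times", "denominator": "number of medication orders", "units": "min"},
  "SH16": {"kind": "binary", "metric": "availability of compliant ambulances", "condition": "available", "units": ""},
  "SH17": {"kind": "binary", "metric": "implementation of sterilization protocols", "condition": "implemented", "units": ""},
  "SH18": {"kind": "count", "metric": "functioning non-core activities", "units": "activities"},
  "SH19": {"kind": "count", "metric": "available positions for ED specialists", "units": "positions"},
  "SH20": {"kind": "count", "metric": "available positions for ED general physicians", "units": "positions"},
  "SH21": {"kind": "ratio-percent", "metric": "% of medical staff with ALS certification", "numerator": "certified staff", "denominator": "total medical staff", "units": "%"},
  "SH22": {"kind": "count", "metric": "available positions for ED nurses", "units": "positions"},
  "SH23": {"kind": "count", "metric": "accessories and instruments covering outbreak demand", "units": "items"},
  "SH24": {"kind": "ratio-percent", "metric": "inventory service level, medical consumables", "numerator": "satisfied consumable orders", "denominator": "total orders", "units": "%"},
  "SH25": {"kind": "ratio-percent", "metric": "inventory service level, medication", "numerator": "satisfied medication orders", "denominator": "total medication orders", "units": "%"},
  "SH26": {"kind": "ratio-percent", "metric": "bed occupation ratio", "numerator": "occupied outbreak beds", "denominator": "assigned outbreak beds", "units": "%"},
  "SH27": {"kind": "mean-interval", "metric": "average physician waiting time", "numerator": "sum of waits", "denominator": "number of admitted patients", "units": "min"},
  "SH28": {"kind": "ratio-percent", "metric": "patient satisfaction ratio", "numerator": "satisfied patients", "denominator": "admitted patients", "units": "%"},
  "SH29": {"kind": "mean-interval", "metric": "mean length of stay", "numerator": "total length of stay", "denominator": "admitted patients", "units": "h"},
  "SH30": {"kind": "ratio-percent", "metric": "72-hour readmission rate", "numerator": "readmitted patients", "denominator": "admitted patients", "units": "%"},
  "SH31": {"kind": "mean-interval", "metric": "mean waiting time for triage categorization", "numerator": "sum of triage waits", "denominator": "admitted patients", "units": "min"},
  "SH32": {"kind": "mean-interval", "metric": "average monthly intra-hospital infections", "numerator": "annual infections", "denominator": "12 months", "units": "cases/month"},
  "SH33": {"kind": "mean-interval", "metric": "average monthly medication mistakes", "numerator": "annual medication mistakes", "denominator": "12 months", "units": "cases/month"},
  "SH34": {"kind": "mean-interval", "metric": "average monthly diagnosis mistakes", "numerator": "annual diagnosis mistakes", "denominator": "12 months", "units": "cases/month"},
  "SH35": {"kind": "mean-interval", "metric": "average monthly patient misidentification mistakes", "numerator": "annual misidentifications", "denominator": "12 months", "units": "cases/month"}
}
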
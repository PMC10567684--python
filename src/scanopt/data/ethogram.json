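{
  "name": "free-range broiler ethogram",
  "behaviors": [
    {"name": "Roosting", "ontology_id": "ATOL_0000837", "class": "static"},
    {"name": "Resting", "ontology_id": "ATOL_0000816", "class": "static"},
    {"name": "Sleeping", "ontology_id": "ATOL_0000873", "class": "static"},
    {"name": "Walking", "ontology_id": "ATOL_0000805", "class": "active"},
    {"name": "Running", "ontology_id": "ATOL_0000806", "class": "active"},
    {"name": "Hiding", "ontology_id": "ATOL_0000814", "class": "active"},
    {"name": "Feed pecking", "ontology_id": "ATOL_0000363", "class": "eat"},
    {"name": "Drinking", "ontology_id": "ATOL_0000361", "class": "eat"},
    {"name": "Grass pecking", "ontology_id": "ATOL_0000844", "class": "eat"},
    {"name": "Other pecking", "ontology_id": "ATOL_0000845", "class": "eat"},
    {"name": "Self-grooming", "ontology_id": "ATOL_0000823", "class": "comfort"},
    {"name": "Scratching", "ontology_id": "ATOL_0000360", "class": "comfort"},
    {"name": "Stretching", "ontology_id": "ATOL_0000822", "class": "comfort"},
    {"name": "Wing flapping", "ontology_id": "ATOL_0000822", "class": "comfort"},
    {"name": "Swelling", "ontology_id": "ATOL_0005361", "class": "comfort"},
    {"name": "Dust bathing", "ontology_id": "ATOL_0000824", "class": "comfort"},
    {"name": "Attacking", "ontology_id": "ATOL_0000813", "class": "interaction"},
    {"name": "Escaping", "class": "interaction"},
    {"name": "Allo-grooming", "ontology_id": "ATOL_0000826", "class": "interaction"},
    {"name": "Others", "class": "other", "excluded_from_binning": true}
  ],
  "aliases": {
    "Preening": "Self-grooming",
    "Self grooming": "Self-grooming",
    "Fluffing": "Swelling",
    "Allopreening": "Allo-grooming",
    "Wings flapping": "Wing flapping",
    "Other behaviors": "Others"
  }
}
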
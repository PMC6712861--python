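"""Bundled word lists: vocabularies, gazetteers and sampling pools.

Everything here is small, plain-text and shipped with the package so that the
whole pipeline (parsing, rules, synthesis) runs with no download. All of it
is overridable through :class:`ctri_audit.config.AuditConfig` /
:class:`ctri_audit.synthetic_registry.SyntheticConfig`.
"""

from __future__ import annotations

# Tokens that denote an absent value in CTRI free-text fields.  "Not
# applicable" is deliberately NOT here: for the two recruitment-status fields
# it is meaningful data (it is one leg of the truly-foreign criteria), and
# for Phase it maps to the explicit N/A enumeration value.
MISSING_TOKENS: frozenset[str] = frozenset({"nil", "na", "n/a", "not available"})

# The 18 selectable Type of Study categories.  CTRI lets a registrant tick
# several, and the stored value is the undelimited concatenation of the
# ticked labels ("DrugAyurveda"), hence the longest-match tokenizer in
# record_model.  Order here is cosmetic; matching sorts by length.
STUDY_TYPE_VOCAB: tuple[str, ...] = (
    "Drug",
    "Vaccine",
    "Medical Device",
    "Nutraceutical",
    "Biological",
    "Stem Cell Therapy",
    "Surgical/Anesthesia",
    "Diagnostic Agents",
    "Preventive",
    "Screening",
    "Behavioral",
    "Educational/Counseling/Training",
    "Physiotherapy",
    "Ayurveda",
    "Siddha",
    "Unani",
    "Homeopathy",
    "Yoga & Naturopathy",
)

# Country lexicon used for (a) scope classification sampling, (b) foreign
# ethics-committee detection by whole-word match.  Not exhaustive; config
# extensible.
COUNTRIES: tuple[str, ...] = (
    "India",
    "United States of America",
    "USA",
    "United Kingdom",
    "Germany",
    "France",
    "Italy",
    "Spain",
    "Netherlands",
    "Belgium",
    "Switzerland",
    "Austria",
    "Sweden",
    "Denmark",
    "Norway",
    "Finland",
    "Poland",
    "Hungary",
    "Czech Republic",
    "Romania",
    "Bulgaria",
    "Russia",
    "Ukraine",
    "Turkey",
    "Israel",
    "Egypt",
    "South Africa",
    "Kenya",
    "Nigeria",
    "Senegal",
    "Mozambique",
    "Tanzania",
    "Uganda",
    "Ghana",
    "Cote d'Ivoire",
    "Brazil",
    "Argentina",
    "Chile",
    "Peru",
    "Colombia",
    "Mexico",
    "Canada",
    "Australia",
    "New Zealand",
    "Japan",
    "China",
    "South Korea",
    "Taiwan",
    "Thailand",
    "Vietnam",
    "Philippines",
    "Indonesia",
    "Malaysia",
    "Singapore",
    "Sri Lanka",
    "Bangladesh",
    "Nepal",
    "Pakistan",
    "Iran",
    "Saudi Arabia",
    "United Arab Emirates",
    "Georgia",
)

# Country tokens too ambiguous for foreign-EC detection by default
# ("Georgia" is also a personal/State name).
EC_COUNTRY_DENYLIST: frozenset[str] = frozenset({"Georgia"})

# Indian city gazetteer (strict-mode city validation + site sampling).
INDIA_CITIES: tuple[str, ...] = (
    "Mumbai", "Delhi", "Bengaluru", "Hyderabad", "Chennai", "Kolkata",
    "Pune", "Ahmedabad", "Jaipur", "Lucknow", "Kanpur", "Nagpur",
    "Indore", "Bhopal", "Patna", "Vadodara", "Ludhiana", "Agra",
    "Nashik", "Varanasi", "Srinagar", "Amritsar", "Coimbatore",
    "Kochi", "Thiruvananthapuram", "Guwahati", "Chandigarh", "Mysuru",
    "Madurai", "Visakhapatnam", "Surat", "Ranchi", "Raipur", "Dehradun",
    "Jodhpur", "Udaipur", "Shimla", "Manipal", "Vellore", "Puducherry",
)

INDIA_STATES: tuple[str, ...] = (
    "Maharashtra", "Delhi", "Karnataka", "Telangana", "Tamil Nadu",
    "West Bengal", "Gujarat", "Rajasthan", "Uttar Pradesh",
    "Madhya Pradesh", "Bihar", "Punjab", "Kerala", "Assam",
    "Andhra Pradesh", "Jharkhand", "Chhattisgarh", "Uttarakhand",
    "Himachal Pradesh", "Odisha", "Haryana", "Goa",
)

# Person-name pools for the synthetic registry.  SURNAMES are pairwise at
# restricted Damerau-Levenshtein distance >= 3 (verified by a test), so
# distinct synthetic PIs stay distinguishable at every rung of the matching
# ladder at the default max_edit = 2.
FIRST_NAMES: tuple[str, ...] = (
    "Amit", "Rajesh", "Sunil", "Vikram", "Anil", "Suresh", "Ramesh",
    "Prakash", "Deepak", "Manoj", "Sanjay", "Ashok", "Vinod", "Rahul",
    "Arun", "Kiran", "Sunita", "Anita", "Kavita", "Meena", "Priya",
    "Neha", "Pooja", "Shalini", "Rekha", "Lakshmi", "Geeta", "Usha",
    "Radha", "Seema", "Nandini", "Vandana", "Sarita", "Mohan", "Gopal",
    "Harish", "Dinesh", "Mahesh", "Naresh", "Satish",
)

MIDDLE_NAMES: tuple[str, ...] = (
    "Kumar", "Chandra", "Prasanna", "Nath", "Mohan", "Lal", "Devi",
    "Bala", "Raj", "Shankar",
)

SURNAMES: tuple[str, ...] = (
    "Sharma", "Gupta", "Patel", "Reddy", "Iyer", "Nair", "Banerjee",
    "Chatterjee", "Mukherjee", "Deshpande", "Kulkarni", "Joshi", "Mehta",
    "Agarwal", "Bhattacharya", "Srinivasan", "Krishnan", "Menon", "Pillai",
    "Rao", "Singh", "Chauhan", "Chopra", "Kapoor", "Malhotra", "Saxena",
    "Trivedi", "Dubey", "Mishra", "Pandey", "Tiwari", "Yadav", "Verma",
    "Bhatia", "Ghosh", "Bose", "Sen", "Prasad", "Shetty", "Hegde",
    "Kamath", "Fernandes", "Dsouza", "Pereira", "Lobo", "Khan", "Ahmed",
    "Ansari", "Qureshi", "Sheikh", "Rizvi", "Modi", "Thakur", "Rathore",
    "Solanki", "Parmar", "Vaghela", "Gandhi", "Desai", "Vyas", "Pathak",
    "Chaturvedi", "Upadhyay", "Shukla", "Ojha", "Tripathi", "Bajpai",
    "Awasthi", "Nigam", "Sehgal", "Anand", "Arora", "Gill", "Sidhu",
    "Grewal",
)

HONORIFICS: frozenset[str] = frozenset({"dr", "prof", "professor", "mr", "mrs", "ms", "smt", "shri"})

DEGREE_SUFFIXES: frozenset[str] = frozenset(
    {"md", "phd", "mbbs", "ms", "dm", "mch", "dnb", "frcs", "mph", "msc", "do", "dgo"}
)

CORPORATE_SUFFIXES: frozenset[str] = frozenset(
    {"pvt", "ltd", "limited", "inc", "incorporated", "corp", "corporation",
     "india", "private", "co", "as", "llc", "gmbh"}
)

# Sponsor pool: (canonical name, classification) pairs.
SPONSORS: tuple[tuple[str, str], ...] = (
    ("Zenara Pharma Private Limited", "Pharmaceutical industry-Indian"),
    ("Medivista Labs Ltd", "Pharmaceutical industry-Indian"),
    ("Hindustan Therapeutics Pvt Ltd", "Pharmaceutical industry-Indian"),
    ("Calyx Biosciences Limited", "Pharmaceutical industry-Indian"),
    ("Novigen Healthcare Global Inc", "Pharmaceutical industry-Global"),
    ("Orion Remedies Corp", "Pharmaceutical industry-Global"),
    ("Helix Pharma International", "Pharmaceutical industry-Global"),
    ("Axis Clinical Research Organization", "Contract research organization"),
    ("Sterling Trials CRO Pvt Ltd", "Contract research organization"),
    ("Indian Council of Clinical Studies", "Government funding agency"),
    ("National Health Research Board", "Government funding agency"),
    ("Institute of Tropical Medicine Research", "Research institution"),
    ("Metro Medical College and Hospital", "Research institution and hospital"),
    ("Sunrise Charitable Health Trust", "Others"),
)

HOSPITAL_TEMPLATES: tuple[str, ...] = (
    "{city} Institute of Medical Sciences",
    "Government Medical College, {city}",
    "{city} General Hospital",
    "Sacred Heart Hospital, {city}",
    "{city} Memorial Research Centre",
)
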
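concern_id,substance,product_names,index_date,concern_type,grouping_level,grouping_id
immunoglobulin-thromboembolic-2010,human normal immunoglobulin,octagam,2010-08-23,QD,SMQ,embolic and thrombotic events
heparin-anaphylactic-2008,heparin,heparin rotexmedica,2008-02-18,QD,SMQ,anaphylactic reaction
heparin-anaphylactic-2008,heparin,heparin rotexmedica,2008-02-18,QD,SMQ,hypersensitivity
dialysis-out-of-spec-2010,peritoneal dialysis solutions,baxter extraneal;baxter nutrineal;baxter dianeal,2010-10-16,QD,HLT,abdominal and gastrointestinal infections
dialysis-out-of-spec-2010,peritoneal dialysis solutions,baxter extraneal;baxter nutrineal;baxter dianeal,2010-10-16,QD,HLT,peritoneal infections and febrile disorders
epinephrine-incorrect-dose-2013,epinephrine,jext,2013-11-07,QD,SMQ,anaphylactic reaction
epinephrine-incorrect-dose-2013,epinephrine,jext,2013-11-07,QD,SMQ,lack of efficacy/effect
epinephrine-incorrect-dose-2013,epinephrine,jext,2013-11-07,QD,HLGT,product use issues
insulin-out-of-spec-2013,insulin aspart,novomix,2013-10-24,QD,HLGT,glucose metabolism disorders (incl diabetes mellitus)
insulin-out-of-spec-2013,insulin aspart,novomix,2013-10-24,QD,SMQ,hyperglycaemia/new onset diabetes mellitus
insulin-out-of-spec-2013,insulin aspart,novomix,2013-10-24,QD,SMQ,hypoglycaemia
insulin-out-of-spec-2013,insulin aspart,novomix,2013-10-24,QD,HLGT,product use issues
insulin-out-of-spec-2013,insulin aspart,novomix,2013-10-24,QD,SMQ,lack of efficacy/effect
sealant-air-embolism-2010,fibrinogen-containing sealant solutions for spray application,evicel;quixil,2010-06-21,ME,SMQ,medication errors
sealant-air-embolism-2010,fibrinogen-containing sealant solutions for spray application,evicel;quixil,2010-06-21,ME,HLT,non-site specific embolism and thrombosis
sealant-air-embolism-2010,fibrinogen-containing sealant solutions for spray application,evicel;quixil,2010-06-21,ME,HLGT,product use issues
levetiracetam-incorrect-dose-2015,levetiracetam,keppra,2015-12-22,ME,SMQ,medication errors
levetiracetam-incorrect-dose-2015,levetiracetam,keppra,2015-12-22,ME,HLGT,neurological disorders nec
levetiracetam-incorrect-dose-2015,levetiracetam,keppra,2015-12-22,ME,HLGT,product use issues
cabazitaxel-reconstitution-2013,cabazitaxel,jevtana,2013-09-16,ME,SMQ,medication errors
cabazitaxel-reconstitution-2013,cabazitaxel,jevtana,2013-09-16,ME,HLGT,product use issues
adalimumab-incorrect-dose-2013,adalimumab,humira,2013-09-13,ME,SMQ,medication errors
adalimumab-incorrect-dose-2013,adalimumab,humira,2013-09-13,ME,HLGT,product use issues
leuprorelin-incorrect-dose-2013,leuprorelin,eligard,2013-11-06,ME,SMQ,medication errors
leuprorelin-incorrect-dose-2013,leuprorelin,eligard,2013-11-06,ME,HLGT,product use issues
loperamide-abuse-2015,loperamide,,2015-04-23,AM,SMQ,medication errors
loperamide-abuse-2015,loperamide,,2015-04-23,AM,HLGT,product use issues
loperamide-abuse-2015,loperamide,,2015-04-23,AM,HLT,substance-related disorders
loperamide-abuse-2015,loperamide,,2015-04-23,AM,SMQ,drug abuse and dependence
loperamide-abuse-2015,loperamide,,2015-04-23,AM,SMQ,torsade de pointes/qt prolongation
buprenorphine-abuse-2013,buprenorphine,,2013-03-21,AM,HLT,substance-related disorders
buprenorphine-abuse-2013,buprenorphine,,2013-03-21,AM,SMQ,drug abuse and dependence
melatonin-abuse-2011,melatonin,,2011-10-17,AM,SMQ,drug abuse and dependence
melatonin-abuse-2011,melatonin,,2011-10-17,AM,SMQ,psychosis and psychotic disorders
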
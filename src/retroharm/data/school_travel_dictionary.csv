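study_id,variable_id,name,label,description,unit,format,categories,variable_group,wave,respondent
SPEEDY,1,W1_school_travel,Mode of travel to school,How do you usually travel to school?,,categorical,Car;Bus/train;Bicycle;On foot,School_travel,1,child
SPEEDY,2,W1_a2acthrs_clean,Walking to school: duration (hours part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values.",hours,continuous,,School_travel,1,child
SPEEDY,3,W1_a2actmins_clean,Walking to school: duration (minutes part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values.",minutes,continuous,,School_travel,1,child
SPEEDY,4,W1_a3acthrs_clean,Cycling to school: duration (hours part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values.",hours,continuous,,School_travel,1,child
SPEEDY,5,W1_a3actmins_clean,Cycling to school: duration (minutes part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values.",minutes,continuous,,School_travel,1,child
SPEEDY,6,W1_a4acthrs_clean,Travel to school by car or bus: duration (hours part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values. Bus and car journeys were estimated jointly.",hours,continuous,,School_travel,1,child
SPEEDY,7,W1_a4actmins_clean,Travel to school by car or bus: duration (minutes part),"Journey duration item, asked separately per mode prompt; 'clean' denotes range-checked values. Bus and car journeys were estimated jointly.",minutes,continuous,,School_travel,1,child
SPEEDY,8,W1_a2actfreq_clean,Walking to school: frequency,"Journey frequency over the previous 7 days, asked per mode prompt.",,categorical,Never;Once;2 to 3 times;4 or more times,School_travel,1,child
SPEEDY,9,W1_a3actfreq_clean,Cycling to school: frequency,"Journey frequency over the previous 7 days, asked per mode prompt.",,categorical,Never;Once;2 to 3 times;4 or more times,School_travel,1,child
SPEEDY,10,W1_a4actfreq_clean,Travel to school by car or bus: frequency,"Journey frequency over the previous 7 days, asked per mode prompt.",,categorical,Never;Once;2 to 3 times;4 or more times,School_travel,1,child
KISS,1,a_schulweg_hin_sommer,Mode of travel to school during summer,How does your child usually travel to school? Single most common mode. Translated from German.,,categorical,Walk;Cycle/scooter;Car;Bus/train/tram,School_travel,1,parent
KISS,2,a_schulweg_hin_sommer_time,Duration of journey to school,"Journey time by the most direct route, free text in minutes. Translated from German.",minutes,continuous,,School_travel,1,parent
Ballabeina,1,W1_a_schulweg,Mode of travel to school,How does your child make it to school? Translated from French/German.,,categorical,Walk;Cycle/scooter;Bus/tram;Car;Other,School_travel,1,parent
Ballabeina,2,W1_a_langeweg,Duration of journey to school,"One-way trip duration, coarse bands. Translated from French/German.",,categorical,<10 min;10–20 min;>20 min,School_travel,1,parent
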
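section,label,measure,denom,count,printed_pct,note
overall,overall,n,195,195,100,
overall,overall,pain,195,166,85,
overall,overall,nonpharm,195,115,59,
overall,overall,pharm,195,127,65,
overall,overall,opioids,195,25,13,
gender,male,n,143,119,83,
gender,male,pain,119,104,87,
gender,male,nonpharm,119,87,73,
gender,male,pharm,119,100,89,discrepant
gender,male,opioids,119,17,14,
gender,female,n,143,18,13,
gender,female,pain,18,18,100,
gender,female,nonpharm,18,18,100,
gender,female,pharm,18,16,84,discrepant
gender,female,opioids,18,4,22,
gender,other,n,143,6,4,
gender,other,pain,6,6,100,
gender,other,nonpharm,6,4,67,
gender,other,pharm,6,6,100,
gender,other,opioids,6,1,17,
race,nh_white,n,138,110,80,
race,nh_white,pain,110,99,90,
race,nh_white,nonpharm,110,84,76,
race,nh_white,pharm,110,96,87,
race,nh_white,opioids,110,18,16,
race,hispanic,n,138,15,11,
race,hispanic,pain,15,13,87,
race,hispanic,nonpharm,15,10,67,
race,hispanic,pharm,15,11,73,
race,hispanic,opioids,15,0,0,
race,nh_black,n,138,5,4,
race,nh_black,pain,5,4,80,
race,nh_black,nonpharm,5,5,100,
race,nh_black,pharm,5,3,60,
race,nh_black,opioids,5,1,20,
race,other,n,138,8,5,complement
race,other,pain,8,7,88,
race,other,nonpharm,8,5,62,
race,other,pharm,8,7,88,
race,other,opioids,8,1,12,
education,hs_grad,n,145,78,54,
education,hs_grad,pain,78,68,87,
education,hs_grad,nonpharm,78,56,72,
education,hs_grad,pharm,78,67,86,
education,hs_grad,opioids,78,13,17,
education,associates_plus,n,145,37,26,
education,associates_plus,pain,37,33,89,
education,associates_plus,nonpharm,37,31,84,
education,associates_plus,pharm,37,31,84,
education,associates_plus,opioids,37,5,14,
education,trade_vocational,n,145,26,18,
education,trade_vocational,pain,26,25,96,
education,trade_vocational,nonpharm,26,20,77,
education,trade_vocational,pharm,26,21,81,
education,trade_vocational,opioids,26,4,25,discrepant
education,no_hs,n,145,4,2,complement
education,no_hs,pain,4,4,100,
education,no_hs,nonpharm,4,3,75,
education,no_hs,pharm,4,4,100,
education,no_hs,opioids,4,1,25,
job_type,hourly,n,141,77,55,
job_type,hourly,pain,77,71,92,
job_type,hourly,nonpharm,77,61,79,
job_type,hourly,pharm,77,67,87,
job_type,hourly,opioids,77,13,17,
job_type,supervisor,n,141,43,30,
job_type,supervisor,pain,43,38,88,
job_type,supervisor,nonpharm,43,31,72,
job_type,supervisor,pharm,43,36,84,
job_type,supervisor,opioids,43,7,16,
job_type,front_line,n,141,21,15,
job_type,front_line,pain,21,18,86,
job_type,front_line,nonpharm,21,15,71,
job_type,front_line,pharm,21,16,76,
job_type,front_line,opioids,21,2,10,
job_title,laborers,n,139,50,36,
job_title,laborers,pain,50,42,84,
job_title,laborers,nonpharm,50,39,78,
job_title,laborers,pharm,50,42,84,
job_title,laborers,opioids,50,7,14,
job_title,masonry,n,139,25,18,
job_title,masonry,pain,25,23,92,
job_title,masonry,nonpharm,25,19,76,
job_title,masonry,pharm,25,20,80,
job_title,masonry,opioids,25,6,24,
job_title,managers,n,139,19,14,
job_title,managers,pain,19,16,84,
job_title,managers,nonpharm,19,15,79,
job_title,managers,pharm,19,15,79,
job_title,managers,opioids,19,4,21,
job_title,equipment,n,139,12,9,
job_title,equipment,pain,12,11,92,
job_title,equipment,nonpharm,12,10,83,
job_title,equipment,pharm,12,10,83,
job_title,equipment,opioids,12,2,17,
job_title,carpenters,n,139,11,8,
job_title,carpenters,pain,11,11,100,
job_title,carpenters,nonpharm,11,6,55,
job_title,carpenters,pharm,11,11,100,
job_title,carpenters,opioids,11,1,9,
job_title,electricians,n,139,7,5,
job_title,electricians,pain,7,7,100,
job_title,electricians,nonpharm,7,6,86,
job_title,electricians,pharm,7,7,100,
job_title,electricians,opioids,7,1,14,
job_title,other,n,139,15,10,complement
job_title,other,pain,15,14,93,
job_title,other,nonpharm,15,11,73,
job_title,other,pharm,15,12,80,
job_title,other,opioids,15,1,7,
experience,gt20,n,145,80,55,
experience,gt20,pain,80,73,91,
experience,gt20,nonpharm,80,61,76,
experience,gt20,pharm,80,69,86,
experience,gt20,opioids,80,13,16,
experience,11_20,n,145,27,19,
experience,11_20,pain,27,23,85,
experience,11_20,nonpharm,27,18,67,
experience,11_20,pharm,27,22,81,
experience,11_20,opioids,27,6,22,
experience,2_10,n,145,31,21,
experience,2_10,pain,31,27,87,
experience,2_10,nonpharm,31,25,81,
experience,2_10,pharm,31,25,81,
experience,2_10,opioids,31,4,13,
experience,le1,n,145,7,5,
experience,le1,pain,7,7,100,
experience,le1,nonpharm,7,6,86,
experience,le1,pharm,7,7,100,
experience,le1,opioids,7,0,0,
union,yes,n,167,139,83,
union,yes,pain,139,121,87,
union,yes,nonpharm,139,96,69,
union,yes,pharm,139,106,76,
union,yes,opioids,139,21,15,
union,no,n,167,28,17,
union,no,pain,28,23,82,
union,no,nonpharm,28,14,50,
union,no,pharm,28,17,61,
union,no,opioids,28,3,11,
born_us,yes,n,145,139,96,
born_us,yes,pain,139,124,89,
born_us,yes,nonpharm,139,107,77,
born_us,yes,pharm,139,117,84,
born_us,yes,opioids,139,23,17,
born_us,no,n,145,6,4,
born_us,no,pain,6,6,100,
born_us,no,nonpharm,6,3,50,
born_us,no,pharm,6,6,100,
born_us,no,opioids,6,0,0,
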
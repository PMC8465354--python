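0bcca67f8dc485c24b0d1624249cd8c7909b0f289c4668c28fb7e756770aec49  table1.csv
8e41093d83234195f14a5d24c96402fc2ff9e5c3fdf809403a6b3db2f4a2bfea  table2_age_category.csv
3593ddce0513d86eb1aedc604bd84cd0e4bde0f620072d28d48f258d3bb23be2  table2_community.csv
6736bcbdd6bf1381e90b48e4c4a37a61e0c90f09e7c506bd22bbfa6bd931ce01  table2_education.csv
e7e2d11f1a071942ed62711267aff1fd0dac1f419a952c7ee0f094b6157b0122  table2_gender.csv
4150671004e640c12d36b2a40b124634d8d9922c5818858b3a3ebd3a24474632  table2_place.csv
6d35f256f4122199f342a2ac0a243896f4aa395703707a24a3048ddc62781525  table2_printed.csv
82a66c19f4b581092f9a82ffabfb0e550d6ebf72503a894776d7884fcd76d714  table3_printed.csv
36b00f338922a5b86d9bef4d6f398097bdd79c2a0a519fa3d9c288d56ea3aca9  table4.csv
98d2ba986f3ac81471f45437c8ea1e4809f33c5de9606baa54f4ca22202e7c26  table5.csv
777db92794a0fc71f7275d6f135d6542c0922b5bcb71b55461644d655b9a07b8  taxa.csv
94857833329588c4e9e865fda7ddd0d6a9885bb87fab23ec5ccffbe982e1f5d9  use_reports.csv
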